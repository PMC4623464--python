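"""Reading and writing cohort datasets.

Layout of a dataset directory::

    stimuli.csv       per-agent stimulus assignments
    learning.csv      learning-phase trial log
    treatment.csv     treatment-phase trial log
    auction.csv       auction-phase trial log
    debriefs.json     simulated questionnaire records
    ground_truth.csv  agent parameters the simulator injected
    manifest.json     config hash, seed, artifact SHA-256s, timestamps

CSV files are UTF-8 with a header row, "." decimal, 0-based trial indices.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict

import pandas as pd

from . import __version__
from .agents import CohortDataset, SimulatedDebrief
from .config import StudyConfig

__all__ = ["write_dataset", "read_dataset", "write_manifest"]

_CSV_PARTS = ("stimuli", "learning", "treatment", "auction", "ground_truth")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_dataset(dataset: CohortDataset, outdir: str | Path) -> Dict:
    """Write all dataset artifacts plus a run manifest; returns the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for part in _CSV_PARTS:
        getattr(dataset, part).to_csv(out / f"{part}.csv", index=False)
    debriefs = {
        str(aid): dataclasses.asdict(d) for aid, d in sorted(dataset.debriefs.items())
    }
    (out / "debriefs.json").write_text(json.dumps(debriefs, indent=1))
    (out / "config.json").write_text(
        json.dumps(dataset.config.model_dump(), indent=1))
    return write_manifest(out, dataset.config, dataset.seed)


def write_manifest(outdir: Path, config: StudyConfig, seed: int) -> Dict:
    files = sorted(p.name for p in outdir.iterdir()
                   if p.suffix in (".csv", ".json") and p.name != "manifest.json")
    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": seed,
        "artifacts": {name: _sha256(outdir / name) for name in files},
        "written_at": datetime.now(timezone.utc).isoformat(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_dataset(indir: str | Path) -> CohortDataset:
    """Load a dataset directory back into memory (lossless round trip)."""
    d = Path(indir)
    for required in ("treatment.csv", "auction.csv", "stimuli.csv", "debriefs.json"):
        if not (d / required).exists():
            raise FileNotFoundError(f"missing dataset input: {d / required}")
    frames = {}
    for part in _CSV_PARTS:
        path = d / f"{part}.csv"
        frames[part] = pd.read_csv(path) if path.exists() else pd.DataFrame()
    gt = frames["ground_truth"]
    if "known_value_shapes" in gt.columns:  # empty string, not missing
        gt["known_value_shapes"] = gt["known_value_shapes"].fillna("")
    raw = json.loads((d / "debriefs.json").read_text())
    debriefs = {
        int(aid): SimulatedDebrief(
            reported_contingency_feeling=rec["reported_contingency_feeling"],
            named_shapes=[(s, int(lv)) for s, lv in rec["named_shapes"]],
            noticed_stop_pairing=rec["noticed_stop_pairing"],
        )
        for aid, rec in raw.items()
    }
    config = StudyConfig(**json.loads((d / "config.json").read_text()))
    seed = 0
    manifest = d / "manifest.json"
    if manifest.exists():
        seed = json.loads(manifest.read_text()).get("seed", 0)
    return CohortDataset(
        config=config,
        seed=seed,
        stimuli=frames["stimuli"],
        learning=frames["learning"],
        treatment=frames["treatment"],
        auction=frames["auction"],
        debriefs=debriefs,
        ground_truth=frames["ground_truth"],
    )
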