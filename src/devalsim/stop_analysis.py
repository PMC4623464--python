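"""Treatment-phase (stop-signal task) behavioral metrics and exclusions.

SSRT is estimated with the mean method: mean correct-go RT minus mean
presented SSD, which is unbiased when the tracking staircase holds p(stop)
near 0.5. Race-model validity requires failed-stop responses to be faster on
average than go responses (the failed-stop distribution is the go
distribution censored from above by ssd + stop latency).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StopMetrics",
    "compute_stop_metrics",
    "check_race_validity",
    "apply_exclusions",
    "block_monitoring_report",
    "DEFAULT_BOUNDS",
]

#: Default exclusion bounds: p(stop) in [0.4, 0.6], SSRT in [120, 300] ms.
DEFAULT_BOUNDS = {"p_stop": (0.4, 0.6), "ssrt_ms": (120.0, 300.0)}

_GO_OUTCOMES = ("go_response", "go_error", "miss")


@dataclass
class StopMetrics:
    """Per-participant stop-signal task summary."""

    agent_id: int
    go_rt_ms: float
    failed_stop_rt_ms: float
    p_stop: float
    mean_ssd_ms: float
    ssrt_ms: float
    miss_rate: float
    error_rate: float
    n_go: int
    n_stop: int
    mean_ssd_left_ms: float
    mean_ssd_right_ms: float
    race_valid: Optional[bool]
    excluded: bool = False
    exclusion_reason: str = ""


def compute_stop_metrics(log: pd.DataFrame, agent_id: int = 0) -> StopMetrics:
    """Summarize one participant's treatment log.

    Go RT averages correct, non-missed go trials only; mean SSD averages the
    presented SSD over all stop trials pooled across hands (per-hand means
    are also reported); SSRT = go RT − mean SSD (mean method).
    """
    go = log[~log["is_stop_trial"]]
    stop = log[log["is_stop_trial"]]
    if len(go) == 0 or len(stop) == 0:
        raise ValueError("log must contain at least one go and one stop trial")

    go_ok = go[go["outcome"] == "go_response"]
    go_rt = float(go_ok["rt_ms"].mean()) if len(go_ok) else np.nan
    failed = stop[stop["outcome"] == "failed_stop"]
    failed_rt = float(failed["rt_ms"].mean()) if len(failed) else np.nan
    p_stop = float((stop["outcome"] == "successful_stop").mean())
    mean_ssd = float(stop["ssd_ms"].mean())
    left = stop[stop["side"] == "left"]["ssd_ms"]
    right = stop[stop["side"] == "right"]["ssd_ms"]

    race_valid: Optional[bool]
    if len(failed) == 0 or len(go_ok) == 0:
        race_valid = None  # indeterminate without failed stops
    else:
        race_valid = bool(failed_rt < go_rt)

    return StopMetrics(
        agent_id=agent_id,
        go_rt_ms=go_rt,
        failed_stop_rt_ms=failed_rt,
        p_stop=p_stop,
        mean_ssd_ms=mean_ssd,
        ssrt_ms=go_rt - mean_ssd,
        miss_rate=float((go["outcome"] == "miss").mean()),
        error_rate=float((go["outcome"] == "go_error").mean()),
        n_go=len(go),
        n_stop=len(stop),
        mean_ssd_left_ms=float(left.mean()) if len(left) else np.nan,
        mean_ssd_right_ms=float(right.mean()) if len(right) else np.nan,
        race_valid=race_valid,
    )


def compute_cohort_metrics(treatment: pd.DataFrame) -> List[StopMetrics]:
    """Metrics for every ``agent_id`` in a concatenated treatment log."""
    return [
        compute_stop_metrics(g, agent_id=aid)
        for aid, g in treatment.groupby("agent_id", sort=True)
    ]


def metrics_frame(metrics: List[StopMetrics]) -> pd.DataFrame:
    return pd.DataFrame([asdict(m) for m in metrics])


def check_race_validity(metrics: List[StopMetrics]) -> Dict:
    """Cohort-level race-model check: paired t-test of mean go RT vs mean
    failed-stop RT across participants, with Cohen's d_z.

    Returns per-participant flags plus the cohort test (df = n − 1).
    """
    usable = [m for m in metrics if m.race_valid is not None]
    go = np.array([m.go_rt_ms for m in usable])
    failed = np.array([m.failed_stop_rt_ms for m in usable])
    out: Dict = {
        "per_participant": {m.agent_id: m.race_valid for m in metrics},
        "n": len(usable),
        "fraction_valid": float(np.mean([m.race_valid for m in usable]))
        if usable else np.nan,
    }
    if len(usable) >= 2:
        diff = go - failed
        t, p = stats.ttest_rel(go, failed)
        out.update(
            t=float(t), df=len(usable) - 1, p=float(p),
            cohen_d=float(diff.mean() / diff.std(ddof=1)),
            effect_size_formula="d_z = mean(diff)/sd(diff)",
        )
    return out


def apply_exclusions(
    metrics: List[StopMetrics],
    bounds: Optional[Dict[str, Tuple[float, float]]] = None,
    require_race_valid: bool = True,
) -> Tuple[List[StopMetrics], pd.DataFrame]:
    """Flag and drop participants with atypical stopping behavior.

    Defaults: p(stop) within [0.4, 0.6], SSRT within [120, 300] ms, and a
    valid race-model pattern (failed-stop RT < go RT). Returns the retained
    metrics and an exclusion report (one row per excluded participant).
    """
    bounds = bounds or DEFAULT_BOUNDS
    retained, report = [], []
    for m in metrics:
        reasons = []
        for fieldname, (lo, hi) in bounds.items():
            v = getattr(m, fieldname)
            if not lo <= v <= hi:
                reasons.append(fieldname.replace("_ms", ""))
        if require_race_valid and m.race_valid is not True:
            reasons.append("race_invalid")
        if reasons:
            m.excluded = True
            m.exclusion_reason = ",".join(reasons)
            report.append(dict(agent_id=m.agent_id, reason=m.exclusion_reason,
                               p_stop=m.p_stop, ssrt_ms=m.ssrt_ms))
        else:
            retained.append(m)
    return retained, pd.DataFrame(report, columns=["agent_id", "reason",
                                                   "p_stop", "ssrt_ms"])


def block_monitoring_report(
    log: pd.DataFrame,
    go_rt_band: Tuple[float, float] = (400.0, 650.0),
    p_stop_band: Tuple[float, float] = (0.4, 0.6),
    min_ssd_ms: float = 100.0,
) -> pd.DataFrame:
    """Per-block warning report mirroring the experimenter's online
    monitoring targets (go RT 400–650 ms, p(stop) 0.4–0.6, SSD > 100 ms).
    Warnings only — never an exclusion."""
    rows = []
    for block, g in log.groupby("block"):
        go_ok = g[(~g["is_stop_trial"]) & (g["outcome"] == "go_response")]
        stop = g[g["is_stop_trial"]]
        go_rt = float(go_ok["rt_ms"].mean()) if len(go_ok) else np.nan
        p_stop = float((stop["outcome"] == "successful_stop").mean()) if len(stop) else np.nan
        ssd = float(stop["ssd_ms"].mean()) if len(stop) else np.nan
        warnings = []
        if np.isfinite(go_rt) and not go_rt_band[0] <= go_rt <= go_rt_band[1]:
            warnings.append("go_rt")
        if np.isfinite(p_stop) and not p_stop_band[0] <= p_stop <= p_stop_band[1]:
            warnings.append("p_stop")
        if np.isfinite(ssd) and ssd <= min_ssd_ms:
            warnings.append("ssd")
        rows.append(dict(block=block, go_rt_ms=go_rt, p_stop=p_stop,
                         mean_ssd_ms=ssd, warnings=",".join(warnings)))
    return pd.DataFrame(rows)
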