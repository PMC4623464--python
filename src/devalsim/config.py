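"""Study design configuration.

The experiment has three phases. In the *learning phase*, eight colored
geometric shapes are each associated with one of four mean monetary values by
a fixed reward schedule (two shapes per value level). In the *treatment
phase* the participant performs a stop-signal task on the same shapes; one
shape per value level is paired with stop signals on a fixed fraction of its
trials, the other never. In the *auction phase* the participant repeatedly
bids on each shape, choosing one of six offered cent amounts drawn from five
bid sets.

:class:`StudyConfig` captures every design parameter. Two named presets ship
with the package, reflecting the two data-collection cohorts of the original
design (the second cohort received more value training):

``cohortA``
    50 learning trials per shape (40 rewarded / 10 zero-reward) in 4 blocks;
    36 treatment trials per shape in 8 blocks; 80 auction trials in 4 blocks.
``cohortB``
    72 learning trials per shape (60 rewarded / 12 zero-reward) in 6 blocks;
    44 treatment trials per shape in 11 blocks; 80 auction trials in 4 blocks.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List

from pydantic import BaseModel, field_validator, model_validator

__all__ = [
    "SHAPES",
    "COLORS",
    "StudyConfig",
    "StimulusSpec",
    "get_preset",
    "PRESET_NAMES",
]

SHAPES = (
    "square",
    "circle",
    "diamond",
    "triangle",
    "inverted_triangle",
    "cross",
    "hexagon",
    "i_shape",
)

COLORS = ("white", "green", "blue", "yellow", "cyan", "magenta", "orange", "gray")

#: Five ascending six-amount bid sets (cents) offered in the auction phase.
DEFAULT_BID_SETS = (
    (34, 68, 102, 136, 170, 204),
    (39, 78, 117, 156, 195, 234),
    (44, 88, 132, 176, 220, 264),
    (49, 98, 147, 196, 245, 294),
    (54, 108, 162, 216, 270, 324),
)

#: Trained mean values in cents, low to high ($0.50, $1, $2, $4).
DEFAULT_VALUE_MEANS = (40, 80, 160, 320)


class StudyConfig(BaseModel):
    """All design parameters of one study run.

    Counts are per shape unless noted; durations are milliseconds; amounts
    are integer cents.
    """

    learning_trials_per_shape: int
    learning_zero_reward_trials_per_shape: int
    learning_blocks: int
    treatment_trials_per_shape: int
    treatment_blocks: int
    stop_fraction_on_stop_shapes: float = 0.75
    auction_presentations_per_shape: int = 10
    auction_blocks: int = 4
    value_means_cents: List[int] = list(DEFAULT_VALUE_MEANS)
    reward_dispersion_cents: int = 25
    ssd_initial_ms: int = 250
    ssd_step_ms: int = 50
    ssd_floor_ms: int = 0
    ssd_ceiling_ms: int = 900
    bid_sets: List[List[int]] = [list(s) for s in DEFAULT_BID_SETS]
    response_deadline_ms: int = 1000
    rng_seed: int = 0

    @field_validator("value_means_cents")
    @classmethod
    def _means_increasing(cls, v):
        if len(v) != 4 or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("value_means_cents must be 4 strictly increasing amounts")
        return v

    @field_validator("bid_sets")
    @classmethod
    def _bid_sets_valid(cls, v):
        for s in v:
            if len(s) != 6 or any(b <= a for a, b in zip(s, s[1:])):
                raise ValueError("each bid set must be 6 strictly increasing amounts")
        return v

    @field_validator("stop_fraction_on_stop_shapes")
    @classmethod
    def _fraction_valid(cls, v):
        if not 0.0 <= v <= 1.0:
            raise ValueError("stop_fraction_on_stop_shapes must be in [0, 1]")
        return v

    @model_validator(mode="after")
    def _counts_consistent(self):
        if self.learning_zero_reward_trials_per_shape > self.learning_trials_per_shape:
            raise ValueError("zero-reward count exceeds learning trials per shape")
        return self

    def config_hash(self) -> str:
        """Stable SHA-256 over the canonical JSON form."""
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        """Load a configuration from a JSON (or JSON-compatible YAML) file."""
        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml  # optional; only needed for YAML configs

            data = yaml.safe_load(text)
        return cls(**data)


_PRESETS = {
    "cohortA": dict(
        learning_trials_per_shape=50,
        learning_zero_reward_trials_per_shape=10,
        learning_blocks=4,
        treatment_trials_per_shape=36,
        treatment_blocks=8,
    ),
    "cohortB": dict(
        learning_trials_per_shape=72,
        learning_zero_reward_trials_per_shape=12,
        learning_blocks=6,
        treatment_trials_per_shape=44,
        treatment_blocks=11,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def get_preset(name: str, **overrides) -> StudyConfig:
    """Return a named preset configuration, optionally overriding fields."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
    params = dict(_PRESETS[name])
    params.update(overrides)
    return StudyConfig(**params)


class StimulusSpec(BaseModel):
    """One of the eight color-shape stimuli with its trained value and
    stop-pairing assignment."""

    shape_id: str
    color_id: str
    value_level: int  # 1 (low) .. 4 (high)
    mean_value_cents: int
    stop_paired: bool

    @field_validator("value_level")
    @classmethod
    def _level_valid(cls, v):
        if not 1 <= v <= 4:
            raise ValueError("value_level must be 1..4")
        return v
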