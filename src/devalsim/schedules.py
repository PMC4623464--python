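"""Randomized, reproducible trial schedules for the three phases.

Every generator is a pure function of ``(config, stimuli, seed)``: the same
inputs produce byte-identical schedules. Schedules are plain pandas
DataFrames with one row per trial, using the column names of the CSV
interchange format (0-based ``trial_index``, mandatory header on disk).
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np
import pandas as pd

from .config import COLORS, SHAPES, StimulusSpec, StudyConfig

__all__ = [
    "assign_stimuli",
    "generate_learning_schedule",
    "generate_treatment_schedule",
    "generate_auction_schedule",
    "AUCTION_KEYS",
]

#: Response keys for the six auction bids, left to right on the keyboard.
AUCTION_KEYS = ("r", "t", "y", "u", "i", "o")


class ScheduleConfigError(ValueError):
    """Raised when a configuration cannot produce a valid schedule."""


def assign_stimuli(
    config: StudyConfig, rng_seed: int | np.random.Generator
) -> List[StimulusSpec]:
    """Randomly pair shapes with colors, assign pairs to the four value
    levels, and mark one stimulus per level as stop-paired.

    Each shape and each color is used exactly once; each value level gets
    exactly two stimuli, exactly one of which is stop-paired.
    """
    rng = _as_rng(rng_seed)
    colors = list(COLORS)
    shapes = list(SHAPES)
    rng.shuffle(colors)
    order = rng.permutation(len(shapes))
    stop_choice = rng.integers(0, 2, size=4)  # which of each level pair stops

    specs: List[StimulusSpec] = []
    for i, idx in enumerate(order):
        level = i // 2 + 1
        specs.append(
            StimulusSpec(
                shape_id=shapes[idx],
                color_id=colors[idx],
                value_level=level,
                mean_value_cents=config.value_means_cents[level - 1],
                stop_paired=(i % 2) == stop_choice[level - 1],
            )
        )
    specs.sort(key=lambda s: (s.value_level, not s.stop_paired))
    return specs


def stimuli_frame(stimuli: Sequence[StimulusSpec]) -> pd.DataFrame:
    """Tabular view of a stimulus assignment (the stop-assignment CSV)."""
    return pd.DataFrame([s.model_dump() for s in stimuli])


def generate_learning_schedule(
    config: StudyConfig,
    stimuli: Sequence[StimulusSpec],
    rng_seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Learning-phase schedule: per shape, ``learning_trials_per_shape``
    trials of which exactly ``learning_zero_reward_trials_per_shape`` pay
    zero; the rest pay integer cents uniform on [mean-d, mean+d].

    Quadrants are balanced exactly when the per-shape count divides by 4,
    otherwise sampled i.i.d. uniform. Trials are globally shuffled, then cut
    into ``learning_blocks`` contiguous equal blocks.
    """
    rng = _as_rng(rng_seed)
    n = config.learning_trials_per_shape
    n_zero = config.learning_zero_reward_trials_per_shape
    total = n * len(stimuli)
    if n == 0:
        return _empty_learning_frame()
    if total % config.learning_blocks != 0:
        raise ScheduleConfigError(
            f"{total} learning trials not divisible into {config.learning_blocks} blocks"
        )

    d = config.reward_dispersion_cents
    rows = []
    for spec in stimuli:
        rewards = rng.integers(
            spec.mean_value_cents - d, spec.mean_value_cents + d + 1, size=n
        )
        zero_idx = rng.choice(n, size=n_zero, replace=False)
        rewards[zero_idx] = 0
        if n % 4 == 0:
            quadrants = np.tile(np.arange(1, 5), n // 4)
            rng.shuffle(quadrants)
        else:
            quadrants = rng.integers(1, 5, size=n)
        for q, r in zip(quadrants, rewards):
            rows.append((spec.shape_id, spec.color_id, spec.value_level,
                         spec.stop_paired, int(q), int(r)))

    df = pd.DataFrame(
        rows,
        columns=["shape_id", "color_id", "value_level", "stop_paired",
                 "quadrant", "scheduled_reward_cents"],
    )
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df.insert(0, "trial_index", np.arange(len(df)))
    df.insert(1, "block", df["trial_index"] // (total // config.learning_blocks))
    return df


def generate_treatment_schedule(
    config: StudyConfig,
    stimuli: Sequence[StimulusSpec],
    rng_seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Treatment-phase (stop-signal task) schedule.

    Stop-paired stimuli receive exactly ``stop_fraction × trials_per_shape``
    stop trials (the product must be integral); never-stopped stimuli receive
    none. Sides are balanced per stimulus, and stop trials are stratified
    across sides as evenly as the odd/even split allows.
    """
    rng = _as_rng(rng_seed)
    n = config.treatment_trials_per_shape
    if n == 0:
        return _empty_treatment_frame()
    total = n * len(stimuli)
    if total % config.treatment_blocks != 0:
        raise ScheduleConfigError(
            f"{total} treatment trials not divisible into {config.treatment_blocks} blocks"
        )
    n_stop_f = config.stop_fraction_on_stop_shapes * n
    if abs(n_stop_f - round(n_stop_f)) > 1e-9:
        raise ScheduleConfigError(
            f"stop fraction {config.stop_fraction_on_stop_shapes} x {n} trials "
            "is not an integer stop-trial count"
        )
    n_stop = int(round(n_stop_f))

    rows = []
    for spec in stimuli:
        if n % 2 == 0:
            sides = np.array(["left", "right"]).repeat(n // 2)
        else:
            sides = np.array(["left", "right"]).repeat(n // 2)
            sides = np.append(sides, rng.choice(["left", "right"]))
        rng.shuffle(sides)
        is_stop = np.zeros(n, dtype=bool)
        if spec.stop_paired and n_stop > 0:
            # stratify stop trials across sides (split rounds randomly)
            left_idx = np.flatnonzero(sides == "left")
            right_idx = np.flatnonzero(sides == "right")
            n_left = n_stop // 2
            if n_stop % 2 == 1:
                n_left += int(rng.integers(0, 2))
            n_left = min(n_left, len(left_idx))
            n_right = min(n_stop - n_left, len(right_idx))
            is_stop[rng.choice(left_idx, size=n_left, replace=False)] = True
            is_stop[rng.choice(right_idx, size=n_right, replace=False)] = True
        for s, st in zip(sides, is_stop):
            rows.append((spec.shape_id, spec.color_id, spec.value_level,
                         spec.stop_paired, s, bool(st)))

    df = pd.DataFrame(
        rows,
        columns=["shape_id", "color_id", "value_level", "stop_paired",
                 "side", "is_stop_trial"],
    )
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df.insert(0, "trial_index", np.arange(len(df)))
    df.insert(1, "block", df["trial_index"] // (total // config.treatment_blocks))
    return df


def generate_auction_schedule(
    config: StudyConfig,
    stimuli: Sequence[StimulusSpec],
    rng_seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Auction-phase schedule: each (stimulus, bid-set) pair occurs exactly
    twice, with a fresh random button permutation of the six amounts on each
    trial."""
    rng = _as_rng(rng_seed)
    n_sets = len(config.bid_sets)
    per_shape = config.auction_presentations_per_shape
    if per_shape != 2 * n_sets:
        raise ScheduleConfigError(
            f"auction_presentations_per_shape ({per_shape}) must be twice the "
            f"number of bid sets ({n_sets})"
        )
    total = per_shape * len(stimuli)
    if total % config.auction_blocks != 0:
        raise ScheduleConfigError(
            f"{total} auction trials not divisible into {config.auction_blocks} blocks"
        )

    rows = []
    for spec in stimuli:
        for set_id in range(1, n_sets + 1):
            for _ in range(2):
                amounts = np.array(config.bid_sets[set_id - 1])
                perm = rng.permutation(6)
                mapping = "|".join(
                    f"{k}:{amounts[p]}" for k, p in zip(AUCTION_KEYS, perm)
                )
                rows.append((spec.shape_id, spec.color_id, spec.value_level,
                             spec.stop_paired, set_id, mapping))

    df = pd.DataFrame(
        rows,
        columns=["shape_id", "color_id", "value_level", "stop_paired",
                 "bid_set_id", "button_mapping"],
    )
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df.insert(0, "trial_index", np.arange(len(df)))
    df.insert(1, "block", df["trial_index"] // (total // config.auction_blocks))
    return df


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _empty_learning_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["trial_index", "block", "shape_id", "color_id", "value_level",
                 "stop_paired", "quadrant", "scheduled_reward_cents"]
    )


def _empty_treatment_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["trial_index", "block", "shape_id", "color_id", "value_level",
                 "stop_paired", "side", "is_stop_trial"]
    )
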