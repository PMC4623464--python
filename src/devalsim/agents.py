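"""Simulated participants: race-model motor behavior plus knowledge-dependent
valuation.

An agent's motor behavior follows the independent horse-race model of
response inhibition: on every trial a go process and (on stop trials) a stop
process race, and the response is cancelled iff the stop process finishes
first. Go reaction times and stop latencies are ex-Gaussian (normal +
exponential), the standard parametric family for reaction-time data; the mean
of the stop-latency distribution is the agent's true stop-signal reaction
time (SSRT).

Valuation: during the learning phase the agent builds an internal value
estimate per shape (the mean of the non-zero rewards it observed; scheduled
zero-reward trials are treated as omissions). In the auction phase the
subjective worth of a shape is::

    worth = value_sensitivity * internal_value * (1 - devaluation) + noise

where ``devaluation`` applies only to stop-paired shapes and may be larger
for shapes whose value the agent can explicitly name, and the Gaussian bid
noise is smaller for named shapes. The chosen bid is the offered amount
closest to the worth (ties go to the lower amount).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import StimulusSpec, StudyConfig
from .schedules import (
    assign_stimuli,
    generate_auction_schedule,
    generate_learning_schedule,
    generate_treatment_schedule,
    stimuli_frame,
)

__all__ = [
    "AgentProfile",
    "StaircaseState",
    "SimulatedDebrief",
    "PopulationParams",
    "race_trial",
    "staircase_update",
    "simulate_learning_phase",
    "simulate_treatment_phase",
    "simulate_auction_phase",
    "sample_agent",
    "simulate_cohort",
    "CohortDataset",
]


@dataclass
class AgentProfile:
    """Race-model and valuation parameters of one simulated participant.

    Distribution parameters are ex-Gaussian (mu, sigma, tau) in ms. The
    agent's true SSRT equals ``stop_mu + stop_tau`` (the ex-Gaussian mean).
    """

    go_mu: float = 410.0
    go_sigma: float = 60.0
    go_tau: float = 60.0
    stop_mu: float = 160.0
    stop_sigma: float = 25.0
    stop_tau: float = 35.0
    miss_rate: float = 0.006
    error_rate: float = 0.002
    knowledge: str = "implicit"  # "explicit" | "implicit"
    known_value_shapes: Tuple[str, ...] = ()
    value_sensitivity: float = 1.0
    bid_noise_sd: float = 50.0
    bid_noise_sd_known: float = 25.0
    devaluation_effect: float = 0.0
    devaluation_effect_known: float = 0.0
    stop_contingency_aware: bool = False
    rng_seed: int = 0
    internal_values: Optional[Dict[str, float]] = None

    def __post_init__(self):
        for p in (self.miss_rate, self.error_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must be probabilities")
        for e in (self.devaluation_effect, self.devaluation_effect_known):
            if not 0.0 <= e < 1.0:
                raise ValueError("devaluation effects must lie in [0, 1)")
        for v in (self.go_mu, self.go_sigma, self.go_tau,
                  self.stop_mu, self.stop_sigma, self.stop_tau,
                  self.bid_noise_sd, self.bid_noise_sd_known):
            if v < 0:
                raise ValueError("distribution parameters must be non-negative")
        if self.knowledge not in ("explicit", "implicit"):
            raise ValueError("knowledge must be 'explicit' or 'implicit'")

    @property
    def true_ssrt(self) -> float:
        return self.stop_mu + self.stop_tau

    @property
    def mean_go_rt(self) -> float:
        return self.go_mu + self.go_tau


@dataclass
class StaircaseState:
    """Per-hand stop-signal delays (ms)."""

    ssd_left_ms: float
    ssd_right_ms: float


@dataclass
class SimulatedDebrief:
    """Simulated answers to the post-experimental awareness questionnaire."""

    reported_contingency_feeling: bool
    named_shapes: List[Tuple[str, int]]  # (shape_id, claimed value level 1..4)
    noticed_stop_pairing: bool


def race_trial(
    go_rt: float,
    stop_latency: Optional[float] = None,
    ssd: Optional[float] = None,
    deadline: Optional[float] = None,
) -> Tuple[str, Optional[float]]:
    """Resolve one trial of the independent race between go and stop.

    Returns ``(outcome, rt)`` where outcome is ``"go_response"``/``"miss"``
    on go trials and ``"successful_stop"``/``"failed_stop"`` on stop trials.
    A stop wins on ties (``ssd + stop_latency == go_rt``); a go process that
    would miss the deadline cannot produce a response, so on stop trials it
    counts as a successful stop.
    """
    if go_rt < 0 or (ssd is not None and ssd < 0):
        raise ValueError("go_rt and ssd must be non-negative")
    missed = deadline is not None and go_rt > deadline
    if ssd is None:
        return ("miss", None) if missed else ("go_response", go_rt)
    if stop_latency is None:
        raise ValueError("stop trials require a stop_latency sample")
    if missed or ssd + stop_latency <= go_rt:
        return ("successful_stop", None)
    return ("failed_stop", go_rt)


def staircase_update(
    state: StaircaseState,
    side: str,
    outcome: str,
    step_ms: float = 50.0,
    floor_ms: float = 0.0,
    ceiling_ms: float = 900.0,
) -> StaircaseState:
    """One ±step update of the tracking staircase for the responding hand.

    The SSD on ``side`` moves up by ``step_ms`` after a successful stop and
    down after a failed stop, clamped to [floor, ceiling]; the other hand's
    SSD is untouched.
    """
    if outcome not in ("successful_stop", "failed_stop"):
        raise ValueError(f"staircase_update called with non-stop outcome {outcome!r}")
    delta = step_ms if outcome == "successful_stop" else -step_ms
    if side == "left":
        new = float(np.clip(state.ssd_left_ms + delta, floor_ms, ceiling_ms))
        return replace(state, ssd_left_ms=new)
    if side == "right":
        new = float(np.clip(state.ssd_right_ms + delta, floor_ms, ceiling_ms))
        return replace(state, ssd_right_ms=new)
    raise ValueError(f"unknown side {side!r}")


def _ex_gaussian(rng, mu, sigma, tau, size):
    out = rng.normal(mu, sigma, size)
    if tau > 0:
        out = out + rng.exponential(tau, size)
    return np.maximum(out, 1.0)


def simulate_learning_phase(
    agent: AgentProfile,
    schedule: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Play the learning phase: every scheduled trial is re-presented until
    answered correctly; the reward is delivered on the completing
    presentation. Updates ``agent.internal_values`` in place (mean of the
    shape's non-zero scheduled rewards)."""
    p_fail = agent.miss_rate + agent.error_rate
    n = len(schedule)
    if p_fail > 0 and n > 0:
        n_repeats = rng.geometric(1.0 - p_fail, size=n) - 1
    else:
        n_repeats = np.zeros(n, dtype=int)

    rows = []
    for i, rec in enumerate(schedule.itertuples(index=False)):
        for a in range(n_repeats[i] + 1):
            is_last = a == n_repeats[i]
            rt = float(_ex_gaussian(rng, agent.go_mu, agent.go_sigma, agent.go_tau, 1)[0])
            if is_last:
                outcome = "correct"
            else:
                p_miss = agent.miss_rate / p_fail
                outcome = "miss" if rng.random() < p_miss else "error"
            rows.append((
                rec.trial_index, rec.block, rec.shape_id, rec.color_id,
                rec.value_level, rec.stop_paired, rec.quadrant,
                rec.scheduled_reward_cents, a,
                np.nan if outcome == "miss" else round(rt, 1),
                outcome == "correct",
                int(rec.scheduled_reward_cents) if is_last else 0,
            ))

    log = pd.DataFrame(rows, columns=[
        "trial_index", "block", "shape_id", "color_id", "value_level",
        "stop_paired", "quadrant", "scheduled_reward_cents",
        "presentation", "rt_ms", "correct", "reward_delivered_cents",
    ])
    nonzero = schedule[schedule["scheduled_reward_cents"] > 0]
    agent.internal_values = (
        nonzero.groupby("shape_id")["scheduled_reward_cents"].mean().to_dict()
    )
    for shape in schedule["shape_id"].unique():
        agent.internal_values.setdefault(shape, 0.0)
    return log


def simulate_treatment_phase(
    agent: AgentProfile,
    schedule: pd.DataFrame,
    config: StudyConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Play the stop-signal treatment phase with per-hand ±step tracking
    staircases starting at ``config.ssd_initial_ms``."""
    n = len(schedule)
    go_rts = _ex_gaussian(rng, agent.go_mu, agent.go_sigma, agent.go_tau, n)
    stop_lats = _ex_gaussian(rng, agent.stop_mu, agent.stop_sigma, agent.stop_tau, n)
    lapse = rng.random(n) < agent.miss_rate
    direrr = rng.random(n) < agent.error_rate
    deadline = config.response_deadline_ms
    go_rts = np.where(lapse, deadline + 1.0, go_rts)  # lapses produce no response

    ssd = {"left": float(config.ssd_initial_ms), "right": float(config.ssd_initial_ms)}
    sides = schedule["side"].to_numpy()
    is_stop = schedule["is_stop_trial"].to_numpy()

    ssd_col = np.full(n, np.nan)
    rt_col = np.full(n, np.nan)
    outcome_col = np.empty(n, dtype=object)
    for i in range(n):
        if is_stop[i]:
            cur = ssd[sides[i]]
            outcome, rt = race_trial(go_rts[i], stop_lats[i], cur, deadline)
            ssd_col[i] = cur
            delta = config.ssd_step_ms if outcome == "successful_stop" else -config.ssd_step_ms
            ssd[sides[i]] = float(
                np.clip(cur + delta, config.ssd_floor_ms, config.ssd_ceiling_ms)
            )
        else:
            outcome, rt = race_trial(go_rts[i], deadline=deadline)
            if outcome == "go_response" and direrr[i]:
                outcome = "go_error"
        outcome_col[i] = outcome
        if rt is not None:
            rt_col[i] = round(rt, 1)

    log = schedule.copy()
    log["ssd_ms"] = ssd_col
    log["outcome"] = outcome_col
    log["rt_ms"] = rt_col
    return log


def simulate_auction_phase(
    agent: AgentProfile,
    schedule: pd.DataFrame,
    stimuli: Sequence[StimulusSpec],
    config: StudyConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Play the auction phase: per trial, compute the noisy subjective worth
    and choose the offered amount closest to it (ties -> lower amount)."""
    if agent.internal_values is None:
        raise ValueError("agent has no internal values; run the learning phase first")
    spec_by_shape = {s.shape_id: s for s in stimuli}
    known = set(agent.known_value_shapes)
    known_levels = {spec_by_shape[s].value_level for s in known if s in spec_by_shape}

    n = len(schedule)
    chosen = np.zeros(n, dtype=int)
    level = np.zeros(n, dtype=int)
    bid_sets = [np.asarray(s) for s in config.bid_sets]
    shapes = schedule["shape_id"].to_numpy()
    set_ids = schedule["bid_set_id"].to_numpy()
    noise = rng.normal(0.0, 1.0, size=n)

    for i in range(n):
        spec = spec_by_shape[shapes[i]]
        value = agent.internal_values[shapes[i]]
        if spec.stop_paired:
            effect = (
                agent.devaluation_effect_known
                if spec.value_level in known_levels
                else agent.devaluation_effect
            )
        else:
            effect = 0.0
        sd = agent.bid_noise_sd_known if shapes[i] in known else agent.bid_noise_sd
        worth = agent.value_sensitivity * value * (1.0 - effect) + sd * noise[i]
        amounts = bid_sets[set_ids[i] - 1]
        idx = int(np.argmin(np.abs(amounts - worth)))  # first min -> lower amount
        chosen[i] = amounts[idx]
        level[i] = idx + 1

    log = schedule.copy()
    log["chosen_amount_cents"] = chosen
    log["bid_level"] = level
    return log


def make_debrief(agent: AgentProfile, stimuli: Sequence[StimulusSpec]) -> SimulatedDebrief:
    """Simulated questionnaire record. Explicit agents report a feeling of
    knowing and correctly name the relative value of their known shapes."""
    spec_by_shape = {s.shape_id: s for s in stimuli}
    named = [
        (shape, spec_by_shape[shape].value_level)
        for shape in agent.known_value_shapes
        if shape in spec_by_shape
    ]
    return SimulatedDebrief(
        reported_contingency_feeling=agent.knowledge == "explicit" and len(named) > 0,
        named_shapes=named,
        noticed_stop_pairing=agent.stop_contingency_aware,
    )


@dataclass
class PopulationParams:
    """Population from which simulated participants are drawn.

    Means/SDs define between-agent normal variation in the ex-Gaussian RT
    parameters (truncated at sensible minima). ``explicit_fraction`` sets the
    share of explicit learners; devaluation effects are proportions of
    internal worth removed from stop-paired shapes.
    """

    go_mu: float = 410.0
    go_mu_sd: float = 25.0
    go_sigma: float = 60.0
    go_sigma_sd: float = 8.0
    go_tau: float = 60.0
    go_tau_sd: float = 15.0
    stop_mu: float = 160.0
    stop_mu_sd: float = 12.0
    stop_sigma: float = 25.0
    stop_sigma_sd: float = 5.0
    stop_tau: float = 35.0
    stop_tau_sd: float = 8.0
    miss_rate: float = 0.006
    error_rate: float = 0.002
    explicit_fraction: float = 22 / 65
    value_sensitivity: float = 1.0
    value_sensitivity_sd: float = 0.05
    bid_noise_sd: float = 50.0
    bid_noise_sd_sd: float = 10.0
    bid_noise_sd_known: float = 25.0
    bid_noise_sd_known_sd: float = 5.0
    erratic_fraction: float = 0.10
    erratic_noise_factor: float = 2.5
    deval_implicit: float = 0.05
    deval_implicit_sd: float = 0.03
    deval_explicit: float = 0.05
    deval_explicit_sd: float = 0.03
    deval_explicit_known: float = 0.18
    deval_explicit_known_sd: float = 0.05
    stop_aware_fraction: float = 8 / 65
    known_level_count_probs: Tuple[float, ...] = (0.45, 0.30, 0.20, 0.05)

    def null_effects(self) -> "PopulationParams":
        """Copy with all injected devaluation effects set to zero."""
        return replace(
            self,
            deval_implicit=0.0, deval_implicit_sd=0.0,
            deval_explicit=0.0, deval_explicit_sd=0.0,
            deval_explicit_known=0.0, deval_explicit_known_sd=0.0,
        )


def _trunc_normal(rng, mean, sd, lo):
    return float(max(rng.normal(mean, sd), lo))


def sample_agent(
    pop: PopulationParams,
    stimuli: Sequence[StimulusSpec],
    rng: np.random.Generator,
    knowledge: str,
    rng_seed: int = 0,
) -> AgentProfile:
    """Draw one agent from the population, with the given knowledge grade."""
    known: Tuple[str, ...] = ()
    if knowledge == "explicit":
        # explicit knowledge always includes an extreme (lowest/highest) value
        n_levels = int(rng.choice([1, 2, 3, 4], p=pop.known_level_count_probs))
        levels = [int(rng.choice([1, 4]))]
        others = [lv for lv in (1, 2, 3, 4) if lv != levels[0]]
        levels += list(rng.choice(others, size=n_levels - 1, replace=False))
        shapes: List[str] = []
        for lv in levels:
            pair = [s.shape_id for s in stimuli if s.value_level == lv]
            if rng.random() < 0.5:
                shapes.extend(pair)
            else:
                shapes.append(pair[int(rng.integers(0, 2))])
        known = tuple(shapes)

    noise_factor = pop.erratic_noise_factor if rng.random() < pop.erratic_fraction else 1.0
    if knowledge == "explicit":
        deval = _trunc_normal(rng, pop.deval_explicit, pop.deval_explicit_sd, 0.0)
        deval_known = _trunc_normal(
            rng, pop.deval_explicit_known, pop.deval_explicit_known_sd, 0.0
        )
    else:
        deval = _trunc_normal(rng, pop.deval_implicit, pop.deval_implicit_sd, 0.0)
        deval_known = deval

    return AgentProfile(
        go_mu=_trunc_normal(rng, pop.go_mu, pop.go_mu_sd, 250.0),
        go_sigma=_trunc_normal(rng, pop.go_sigma, pop.go_sigma_sd, 20.0),
        go_tau=_trunc_normal(rng, pop.go_tau, pop.go_tau_sd, 10.0),
        stop_mu=_trunc_normal(rng, pop.stop_mu, pop.stop_mu_sd, 80.0),
        stop_sigma=_trunc_normal(rng, pop.stop_sigma, pop.stop_sigma_sd, 5.0),
        stop_tau=_trunc_normal(rng, pop.stop_tau, pop.stop_tau_sd, 5.0),
        miss_rate=pop.miss_rate,
        error_rate=pop.error_rate,
        knowledge=knowledge,
        known_value_shapes=known,
        value_sensitivity=_trunc_normal(rng, pop.value_sensitivity,
                                        pop.value_sensitivity_sd, 0.2),
        bid_noise_sd=noise_factor * _trunc_normal(rng, pop.bid_noise_sd,
                                                  pop.bid_noise_sd_sd, 15.0),
        bid_noise_sd_known=noise_factor * _trunc_normal(
            rng, pop.bid_noise_sd_known, pop.bid_noise_sd_known_sd, 8.0),
        devaluation_effect=min(deval, 0.95),
        devaluation_effect_known=min(deval_known, 0.95),
        stop_contingency_aware=bool(rng.random() < pop.stop_aware_fraction),
        rng_seed=rng_seed,
    )


@dataclass
class CohortDataset:
    """Everything one simulated cohort produced, plus its ground truth."""

    config: StudyConfig
    seed: int
    stimuli: pd.DataFrame          # per-agent stimulus assignments
    learning: pd.DataFrame         # concatenated learning logs (agent_id column)
    treatment: pd.DataFrame
    auction: pd.DataFrame
    debriefs: Dict[int, SimulatedDebrief]
    ground_truth: pd.DataFrame     # one row per agent

    def agent_ids(self) -> List[int]:
        return sorted(self.ground_truth["agent_id"].tolist())


def simulate_cohort(
    n_agents: int,
    config: StudyConfig,
    pop: Optional[PopulationParams] = None,
    rng_seed: int = 0,
) -> CohortDataset:
    """Simulate a full cohort through all three phases.

    The number of explicit learners is ``round(explicit_fraction * n)``,
    assigned to random agents. Each agent gets an independently randomized
    stimulus assignment and schedules; all randomness descends from one seed.
    """
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    pop = pop or PopulationParams()
    root = np.random.SeedSequence(rng_seed)
    master = np.random.default_rng(root.spawn(1)[0])

    n_explicit = int(round(pop.explicit_fraction * n_agents))
    grades = np.array(["explicit"] * n_explicit + ["implicit"] * (n_agents - n_explicit))
    master.shuffle(grades)

    stim_frames, learn_frames, treat_frames, auct_frames = [], [], [], []
    debriefs: Dict[int, SimulatedDebrief] = {}
    truth_rows = []
    for agent_id, child in enumerate(root.spawn(n_agents + 1)[1:]):
        rng = np.random.default_rng(child)
        stimuli = assign_stimuli(config, rng)
        agent = sample_agent(pop, stimuli, rng, knowledge=grades[agent_id],
                             rng_seed=agent_id)

        learn_sched = generate_learning_schedule(config, stimuli, rng)
        treat_sched = generate_treatment_schedule(config, stimuli, rng)
        auct_sched = generate_auction_schedule(config, stimuli, rng)

        learn = simulate_learning_phase(agent, learn_sched, rng)
        treat = simulate_treatment_phase(agent, treat_sched, config, rng)
        auct = simulate_auction_phase(agent, auct_sched, stimuli, config, rng)
        debriefs[agent_id] = make_debrief(agent, stimuli)

        for df, frames in ((stimuli_frame(stimuli), stim_frames), (learn, learn_frames),
                           (treat, treat_frames), (auct, auct_frames)):
            df = df.copy()
            df.insert(0, "agent_id", agent_id)
            frames.append(df)

        truth_rows.append(dict(
            agent_id=agent_id,
            knowledge=agent.knowledge,
            true_ssrt_ms=agent.true_ssrt,
            true_mean_go_rt_ms=agent.mean_go_rt,
            devaluation_effect=agent.devaluation_effect,
            devaluation_effect_known=agent.devaluation_effect_known,
            known_value_shapes=";".join(agent.known_value_shapes),
            bid_noise_sd=agent.bid_noise_sd,
            stop_contingency_aware=agent.stop_contingency_aware,
        ))

    return CohortDataset(
        config=config,
        seed=rng_seed,
        stimuli=pd.concat(stim_frames, ignore_index=True),
        learning=pd.concat(learn_frames, ignore_index=True),
        treatment=pd.concat(treat_frames, ignore_index=True),
        auction=pd.concat(auct_frames, ignore_index=True),
        debriefs=debriefs,
        ground_truth=pd.DataFrame(truth_rows),
    )
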