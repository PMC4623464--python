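"""End-to-end analysis: stop-task exclusions, knowledge classification, and
every valuation analysis, reported in sections mirroring a results write-up."""

from __future__ import annotations

import logging
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .agents import CohortDataset, SimulatedDebrief
from .stop_analysis import (
    apply_exclusions,
    check_race_validity,
    compute_cohort_metrics,
    metrics_frame,
)
from .valuation import (
    StatResult,
    bid_cell_summaries,
    classify_knowledge,
    devaluation_scores,
    implicit_variance_devaluation_correlation,
    iqr_outlier_filter,
    mann_whitney_u,
    mixed_anova,
    bidding_variance_analysis,
    wilcoxon_signed_rank,
    within_subjects_pair_analysis,
)

logger = logging.getLogger(__name__)

__all__ = ["analyze_cohort"]


def analyze_cohort(dataset: CohortDataset) -> Dict:
    """Run the complete analysis pipeline on one cohort dataset.

    Steps: per-participant stop metrics and race-model validity; exclusion of
    participants with atypical stopping behavior; knowledge classification
    from the debrief; devaluation scores with per-group IQR outlier removal;
    the 2 (STOPPING) × 4 (VALUE) × 2 (KNOWLEDGE) mixed ANOVA on mean bidding
    level; nonparametric control tests on the unfiltered sample; the
    within-subjects named-pair analysis; the bidding-variance analyses; and
    the implicit-learner variance/devaluation correlation.
    """
    report: Dict = {}

    # ---- treatment phase ---------------------------------------------------
    metrics = compute_cohort_metrics(dataset.treatment)
    race = check_race_validity(metrics)
    retained_metrics, exclusion_report = apply_exclusions(metrics)
    retained_ids = [m.agent_id for m in retained_metrics]
    logger.info("stop-task exclusions: %d of %d participants retained",
                len(retained_ids), len(metrics))
    mdf = metrics_frame(metrics)
    report["treatment_phase"] = {
        "metrics": mdf,
        "group_means": {
            "go_rt_ms": float(mdf["go_rt_ms"].mean()),
            "failed_stop_rt_ms": float(mdf["failed_stop_rt_ms"].mean()),
            "p_stop": float(mdf["p_stop"].mean()),
            "mean_ssd_ms": float(mdf["mean_ssd_ms"].mean()),
            "ssrt_ms": float(mdf["ssrt_ms"].mean()),
        },
        "race_model": race,
        "exclusions": exclusion_report,
        "n_retained": len(retained_ids),
    }

    # ---- knowledge classification -----------------------------------------
    true_levels = {
        aid: dict(zip(g["shape_id"], g["value_level"]))
        for aid, g in dataset.stimuli.groupby("agent_id")
    }
    knowledge = {
        aid: classify_knowledge(dataset.debriefs[aid], true_levels[aid])
        for aid in retained_ids
    }
    explicit_ids = sorted(a for a, k in knowledge.items() if k == "explicit")
    implicit_ids = sorted(a for a, k in knowledge.items() if k == "implicit")
    report["types_of_knowledge"] = {
        "knowledge": knowledge,
        "n_explicit": len(explicit_ids),
        "n_implicit": len(implicit_ids),
    }

    # ---- valuation phase ---------------------------------------------------
    auction = dataset.auction[dataset.auction["agent_id"].isin(retained_ids)]
    scores = devaluation_scores(auction)
    kseries = pd.Series(knowledge).loc[scores.index]
    kept, removed = iqr_outlier_filter(scores, kseries)
    analysis_ids = kept.index.tolist()
    cells = bid_cell_summaries(auction[auction["agent_id"].isin(analysis_ids)])
    cells["knowledge"] = cells["agent_id"].map(knowledge)
    anova = mixed_anova(cells, dv="mean_bid_level", subject="agent_id",
                        within=["stop_paired", "value_level"], between="knowledge")
    report["valuation_phase"] = {
        "devaluation_scores": scores,
        "outliers_removed": removed.index.tolist(),
        "n_analyzed": len(analysis_ids),
        "anova": anova,
        "cell_means": cells.groupby(["knowledge", "stop_paired", "value_level"])
        ["mean_bid_level"].mean().reset_index(),
    }

    # ---- control analyses (nonparametric, outliers included) --------------
    go_means, stop_means = [], []
    for aid in scores.index:
        g = auction[auction["agent_id"] == aid]
        go_means.append(g.loc[~g["stop_paired"], "bid_level"].mean())
        stop_means.append(g.loc[g["stop_paired"], "bid_level"].mean())
    report["control_analyses"] = {
        "stopping_wilcoxon": wilcoxon_signed_rank(go_means, stop_means),
        "knowledge_x_stopping_mann_whitney": mann_whitney_u(
            scores.loc[[a for a in scores.index if knowledge[a] == "explicit"]],
            scores.loc[[a for a in scores.index if knowledge[a] == "implicit"]],
        ),
    }

    # ---- within-subjects analysis of explicit learners --------------------
    named = {aid: [s for s, _ in dataset.debriefs[aid].named_shapes]
             for aid in retained_ids}
    expl_in_analysis = [a for a in explicit_ids if a in analysis_ids]
    try:
        report["within_subjects_analysis"] = within_subjects_pair_analysis(
            auction, named, expl_in_analysis)
    except ValueError as err:
        report["within_subjects_analysis"] = {"error": str(err)}

    # ---- bidding-level variance -------------------------------------------
    report["bidding_level_variance"] = bidding_variance_analysis(
        auction[auction["agent_id"].isin(analysis_ids)],
        {a: knowledge[a] for a in analysis_ids}, named)

    # ---- implicit learners --------------------------------------------------
    implicit_section: Dict = {}
    if len(implicit_ids) >= 3:
        icells = bid_cell_summaries(auction[auction["agent_id"].isin(implicit_ids)])
        implicit_section["anova"] = mixed_anova(
            icells, dv="mean_bid_level", subject="agent_id",
            within=["stop_paired", "value_level"])
    if len(implicit_ids) >= 10:
        try:
            implicit_section["variance_correlation"] = (
                implicit_variance_devaluation_correlation(auction, implicit_ids))
        except ValueError as err:
            implicit_section["variance_correlation"] = {"error": str(err)}
    report["implicit_learners"] = implicit_section
    return report


def format_cell_table(report: Dict) -> str:
    """Mean bidding level per KNOWLEDGE × STOPPING × VALUE cell, as text."""
    cells = report["valuation_phase"]["cell_means"]
    wide = cells.pivot_table(index=["knowledge", "stop_paired"],
                             columns="value_level", values="mean_bid_level")
    wide.columns = [f"value_{c}" for c in wide.columns]
    return wide.round(2).to_string()
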