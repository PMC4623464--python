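"""Auction-phase dependent variables, knowledge classification, and the full
statistical pipeline.

The dependent variable is the *bidding level*: the rank (1–6) of the chosen
amount within that trial's ascending set of six offered bids. Because each
STOPPING (0% vs 75% stop-paired) × VALUE (four trained value levels) cell
contains exactly one shape, per-cell summaries are per-shape summaries.

The central test is a mixed-design ANOVA with within-subjects factors
STOPPING (2) and VALUE (4) and the between-subjects factor KNOWLEDGE
(explicit vs implicit learner), dependent variable mean bidding level.
Effect sizes are partial eta squared for ANOVA effects, r = Z/sqrt(N) for
the nonparametric tests, and Cohen's d (d_z for paired contrasts) for
t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "StatResult",
    "bid_to_level",
    "classify_knowledge",
    "bid_cell_summaries",
    "devaluation_scores",
    "iqr_outlier_filter",
    "mixed_anova",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "r_from_z",
    "within_subjects_pair_analysis",
    "bidding_variance_analysis",
    "implicit_variance_devaluation_correlation",
]


@dataclass
class StatResult:
    """One reported test statistic with its effect size and formula tag."""

    name: str
    statistic: str            # "F" | "t" | "z" | "U" | "r_pearson"
    value: float
    df: Optional[float] = None
    df2: Optional[float] = None
    n: Optional[int] = None
    p: Optional[float] = None
    effect_size: Optional[float] = None
    effect_size_name: Optional[str] = None
    effect_size_formula: Optional[str] = None

    def to_dict(self) -> Dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# dependent variable and classification
# ---------------------------------------------------------------------------

def bid_to_level(chosen_amount: int, bid_set: Sequence[int]) -> int:
    """Rank (1 = lowest, 6 = highest) of the chosen amount in its bid set.

    Invariant to the on-screen button permutation, which maps keys to
    amounts but never changes the amounts themselves.
    """
    amounts = list(bid_set)
    if any(b <= a for a, b in zip(amounts, amounts[1:])):
        raise ValueError("bid set must be strictly increasing")  # no rank ties
    if chosen_amount not in amounts:
        raise ValueError(f"amount {chosen_amount} not in bid set {amounts}")
    return amounts.index(chosen_amount) + 1


def classify_knowledge(debrief, true_levels: Mapping[str, int]) -> str:
    """Explicit learner iff the participant reported a feeling of knowing
    AND accurately named the relative value of at least one shape."""
    if not debrief.reported_contingency_feeling:
        return "implicit"
    for shape, claimed in debrief.named_shapes:
        if true_levels.get(shape) == claimed:
            return "explicit"
    return "implicit"


def bid_cell_summaries(auction: pd.DataFrame) -> pd.DataFrame:
    """Per participant, mean and variance of bidding level in each
    STOPPING × VALUE cell (one shape per cell)."""
    g = auction.groupby(["agent_id", "stop_paired", "value_level"])["bid_level"]
    out = g.agg(mean_bid_level="mean", bid_level_variance="var",
                n_bids="count").reset_index()
    return out


def devaluation_scores(auction: pd.DataFrame) -> pd.Series:
    """Per participant: mean bidding level on the four never-stopped shapes
    minus mean level on the four stop-paired shapes (positive values =
    stopping-induced devaluation)."""
    scores = {}
    for aid, g in auction.groupby("agent_id"):
        shapes = g.groupby(["shape_id", "stop_paired"]).size().reset_index()
        if shapes["shape_id"].nunique() != 8 or shapes["stop_paired"].nunique() != 2:
            raise ValueError(f"agent {aid}: auction log does not cover all 8 shapes")
        go = g.loc[~g["stop_paired"], "bid_level"].mean()
        stop = g.loc[g["stop_paired"], "bid_level"].mean()
        scores[aid] = float(go - stop)
    return pd.Series(scores, name="devaluation_score").rename_axis("agent_id")


def iqr_outlier_filter(
    scores: pd.Series,
    groups: pd.Series,
    factor: float = 1.5,
    min_group_size: int = 4,
    quantile_method: str = "linear",
) -> Tuple[pd.Series, pd.Series]:
    """Tukey-fence outlier removal applied within each group separately.

    Values outside [Q1 − factor·IQR, Q3 + factor·IQR] (linear-interpolation
    quartiles by default) are removed. Groups smaller than
    ``min_group_size`` are skipped with a warning.
    """
    keep_mask = pd.Series(True, index=scores.index)
    for label in groups.unique():
        idx = groups[groups == label].index
        vals = scores.loc[idx]
        if len(vals) < min_group_size:
            warnings.warn(
                f"group {label!r} has only {len(vals)} members; outlier filter skipped"
            )
            continue
        q1, q3 = np.percentile(vals, [25, 75], method=quantile_method)
        iqr = q3 - q1
        lo, hi = q1 - factor * iqr, q3 + factor * iqr
        keep_mask.loc[idx] = (vals >= lo) & (vals <= hi)
    return scores[keep_mask], scores[~keep_mask]


# ---------------------------------------------------------------------------
# mixed-design ANOVA
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(levels: int) -> np.ndarray:
    """(levels-1) x levels matrix of orthonormal sum-zero contrasts."""
    return linalg.helmert(levels)


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: Sequence[str],
    between: Optional[str] = None,
) -> pd.DataFrame:
    """Mixed-design ANOVA with one or two within-subjects factors and an
    optional between-subjects factor.

    Classical univariate SS partition: the between factor is tested against
    subjects-within-groups; each within effect (and its interaction with the
    between factor) is tested against its own effect × subject-within-group
    error stratum. With unequal group sizes, within main effects use
    unweighted group means (SPSS Type III convention); with a single between
    factor the between-subjects SS is unambiguous. Requires one observation
    per subject per within-cell (aggregate first; no imputation).

    Returns a table with columns effect, ss_effect, df, ss_error, df_error,
    F, p, eta_p_sq.
    """
    if not 1 <= len(within) <= 2:
        raise ValueError("one or two within-subject factors are supported")
    wide = data.pivot_table(index=subject, columns=list(within), values=dv,
                            aggfunc="mean", sort=True)
    if wide.isna().any().any():
        raise ValueError("missing within-subject cells; no imputation is performed")
    n_cells_expected = int(np.prod([data[w].nunique() for w in within]))
    if wide.shape[1] != n_cells_expected:
        raise ValueError("unbalanced within-subject design")
    counts = data.groupby([subject] + list(within)).size()
    if counts.groupby(subject).size().nunique() != 1:
        raise ValueError("subjects differ in cell coverage")

    Y = wide.to_numpy(float)                      # N x (J*K)
    subjects = wide.index
    if between is not None:
        gmap = data.groupby(subject)[between].first().loc[subjects]
        group_labels = sorted(gmap.unique())
    else:
        gmap = pd.Series("all", index=subjects)
        group_labels = ["all"]
    G = len(group_labels)
    n_g = np.array([(gmap == g).sum() for g in group_labels])
    N = len(subjects)
    g_idx = np.array([group_labels.index(g) for g in gmap])

    if len(within) == 1:
        level_counts = [wide.columns.nunique()]
        wide = wide.reindex(sorted(wide.columns), axis=1)
    else:
        wide = wide.sort_index(axis=1)
        level_counts = [wide.columns.get_level_values(i).nunique()
                        for i in range(len(within))]
    Y = wide.to_numpy(float)  # columns ordered factor1-major, factor2-minor
    bases = []
    for L in level_counts:
        bases.append((_orthonormal_contrasts(L), np.ones((1, L)) / np.sqrt(L)))

    effects: List[Tuple[str, np.ndarray]] = []
    if len(within) == 1:
        effects.append((within[0], bases[0][0]))
    else:
        (H1, u1), (H2, u2) = bases
        effects.append((within[0], np.kron(H1, u2)))
        effects.append((within[1], np.kron(u1, H2)))
        effects.append((f"{within[0]}:{within[1]}", np.kron(H1, H2)))

    rows = []

    # between-subjects stratum
    u = Y.mean(axis=1) * np.sqrt(Y.shape[1])
    ubar_g = np.array([u[g_idx == gi].mean() for gi in range(G)])
    ss_subj = float(sum(((u[g_idx == gi] - ubar_g[gi]) ** 2).sum() for gi in range(G)))
    df_subj = N - G
    if between is not None:
        grand_w = float(u.mean())
        ss_b = float((n_g * (ubar_g - grand_w) ** 2).sum())
        rows.append(_anova_row(between, ss_b, G - 1, ss_subj, df_subj))

    harmonic_factor = G * G / float((1.0 / n_g).sum())
    for name, C in effects:
        Z = Y @ C.T                                # N x q
        q = Z.shape[1]
        zbar_g = np.stack([Z[g_idx == gi].mean(axis=0) for gi in range(G)])
        resid_ss = float(sum(((Z[g_idx == gi] - zbar_g[gi]) ** 2).sum()
                             for gi in range(G)))
        df_err = q * (N - G)
        mu_unw = zbar_g.mean(axis=0)               # unweighted over groups
        ss_eff = float((mu_unw ** 2).sum() * harmonic_factor)
        rows.append(_anova_row(name, ss_eff, q, resid_ss, df_err))
        if between is not None:
            zbar_w = (n_g[:, None] * zbar_g).sum(axis=0) / N
            ss_int = float((n_g[:, None] * (zbar_g - zbar_w) ** 2).sum())
            rows.append(_anova_row(f"{between}:{name}", ss_int, q * (G - 1),
                                   resid_ss, df_err))

    return pd.DataFrame(rows)


def _anova_row(effect, ss, df, ss_err, df_err):
    ms, ms_err = ss / df, ss_err / df_err
    F = ms / ms_err if ms_err > 0 else np.inf
    return dict(
        effect=effect, ss_effect=ss, df=df, ss_error=ss_err, df_error=df_err,
        F=F, p=float(stats.f.sf(F, df, df_err)),
        eta_p_sq=ss / (ss + ss_err) if (ss + ss_err) > 0 else np.nan,
    )


# ---------------------------------------------------------------------------
# nonparametric tests
# ---------------------------------------------------------------------------

def r_from_z(z: float, n: int) -> float:
    """Nonparametric effect size r = Z / sqrt(N)."""
    return float(z / np.sqrt(n))


def _signed_rank_z(d: np.ndarray) -> Tuple[float, float]:
    """Tie-corrected normal-approximation Z for the signed-rank statistic
    (no continuity correction). Returns (W_plus, z)."""
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, t_counts = np.unique(ranks, return_counts=True)
    var -= (t_counts ** 3 - t_counts).sum() / 48.0
    z = (w_plus - mu) / np.sqrt(var) if var > 0 else 0.0
    return w_plus, float(z)


def wilcoxon_signed_rank(
    x: Iterable[float],
    y: Optional[Iterable[float]] = None,
    exact_max_n: int = 25,
) -> StatResult:
    """Wilcoxon signed-rank test on paired values (or precomputed
    differences), reporting Z and r = Z/sqrt(N).

    Zero differences are discarded (classic Wilcoxon treatment). The p-value
    is exact (full sign enumeration) for tie-free samples up to
    ``exact_max_n`` non-zero differences, otherwise from the tie-corrected
    normal approximation. N for the effect size counts all supplied pairs.
    """
    x = np.asarray(list(x), float)
    d = x - np.asarray(list(y), float) if y is not None else x
    n_total = len(d)
    d_nz = d[d != 0]
    if len(d_nz) == 0:
        raise ValueError("all differences are zero")
    w_plus, z = _signed_rank_z(d_nz)

    ranks = stats.rankdata(np.abs(d_nz))
    no_ties = len(np.unique(ranks)) == len(ranks)
    if len(d_nz) <= exact_max_n and no_ties:
        p = float(stats.wilcoxon(d_nz, method="exact").pvalue)
    else:
        p = float(2 * stats.norm.sf(abs(z)))
    return StatResult(
        name="wilcoxon_signed_rank", statistic="z", value=z, n=n_total, p=p,
        effect_size=r_from_z(z, n_total), effect_size_name="r",
        effect_size_formula="r = Z/sqrt(N)",
    )


def mann_whitney_u(
    a: Iterable[float],
    b: Iterable[float],
    exact_max_n: int = 25,
) -> StatResult:
    """Mann-Whitney U test between two independent groups, reporting U, Z
    and r = Z/sqrt(N_total)."""
    a = np.asarray(list(a), float)
    b = np.asarray(list(b), float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    N = n1 + n2
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    _, t_counts = np.unique(combined, return_counts=True)
    tie_term = (t_counts ** 3 - t_counts).sum() / (N * (N - 1)) if N > 1 else 0.0
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    z = (u1 - mu) / np.sqrt(var) if var > 0 else 0.0

    no_ties = len(np.unique(combined)) == N
    method = "exact" if (N <= exact_max_n and no_ties) else "asymptotic"
    p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                                 use_continuity=False).pvalue)
    return StatResult(
        name="mann_whitney_u", statistic="U", value=u1, n=N, p=p,
        df=float(z),  # Z carried alongside U
        effect_size=r_from_z(z, N), effect_size_name="r",
        effect_size_formula="r = Z/sqrt(N)",
    )


# ---------------------------------------------------------------------------
# within-subjects and variance analyses
# ---------------------------------------------------------------------------

def _paired_t(x: np.ndarray, y: np.ndarray, alternative: str = "two-sided",
              name: str = "paired_t") -> StatResult:
    d = x - y
    t, p = stats.ttest_rel(x, y, alternative=alternative)
    sd = d.std(ddof=1)
    return StatResult(
        name=name, statistic="t", value=float(t), df=len(d) - 1, n=len(d),
        p=float(p), effect_size=float(d.mean() / sd) if sd > 0 else np.nan,
        effect_size_name="cohen_d", effect_size_formula="d_z = mean(diff)/sd(diff)",
    )


def within_subjects_pair_analysis(
    auction: pd.DataFrame,
    named_shapes_by_agent: Mapping[int, Sequence[str]],
    explicit_agents: Sequence[int],
) -> Dict:
    """Within explicit learners, compare percent devaluation between
    value-level pairs with at least one explicitly named shape and pairs with
    neither shape named.

    Per value level, percent devaluation = 100 × (L_go − L_stop) / L_go
    where L are mean bidding levels of the never-stopped and stop-paired
    shape of that level. Per participant and condition the median across
    qualifying pairs is taken; participants whose four pairs all fall in one
    condition are excluded. The conditions are compared with a one-sided
    paired t-test (explicit-pair > implicit-pair).
    """
    expl_vals, impl_vals, included = [], [], []
    excluded = []
    for aid in explicit_agents:
        g = auction[auction["agent_id"] == aid]
        named = set(named_shapes_by_agent.get(aid, ()))
        per_cond: Dict[str, List[float]] = {"explicit": [], "implicit": []}
        for level, pair in g.groupby("value_level"):
            l_go = pair.loc[~pair["stop_paired"], "bid_level"].mean()
            l_stop = pair.loc[pair["stop_paired"], "bid_level"].mean()
            pct = 100.0 * (l_go - l_stop) / l_go
            cond = "explicit" if named & set(pair["shape_id"]) else "implicit"
            per_cond[cond].append(pct)
        if per_cond["explicit"] and per_cond["implicit"]:
            expl_vals.append(float(np.median(per_cond["explicit"])))
            impl_vals.append(float(np.median(per_cond["implicit"])))
            included.append(aid)
        else:
            excluded.append(aid)
    if not included:
        raise ValueError("no participant has both pair conditions")

    expl = np.array(expl_vals)
    impl = np.array(impl_vals)
    return {
        "n": len(included),
        "included_agents": included,
        "excluded_agents": excluded,
        "explicit_pair_mean_pct": float(expl.mean()),
        "implicit_pair_mean_pct": float(impl.mean()),
        "explicit_vs_zero": _paired_t(expl, np.zeros_like(expl),
                                      name="explicit_pairs_vs_zero"),
        "implicit_vs_zero": _paired_t(impl, np.zeros_like(impl),
                                      name="implicit_pairs_vs_zero"),
        "explicit_vs_implicit": _paired_t(expl, impl, alternative="greater",
                                          name="explicit_vs_implicit_pairs"),
    }


def bidding_variance_analysis(
    auction: pd.DataFrame,
    knowledge_by_agent: Mapping[int, str],
    named_shapes_by_agent: Mapping[int, Sequence[str]],
) -> Dict:
    """Bidding-level variance as the DV: the same mixed ANOVA as for mean
    bids, plus a named-vs-unnamed paired contrast within explicit learners."""
    cells = bid_cell_summaries(auction)
    cells["knowledge"] = cells["agent_id"].map(knowledge_by_agent)
    anova = mixed_anova(cells, dv="bid_level_variance", subject="agent_id",
                        within=["stop_paired", "value_level"], between="knowledge")

    named_vars, unnamed_vars, agents = [], [], []
    per_shape = auction.groupby(["agent_id", "shape_id"])["bid_level"].var()
    for aid, know in knowledge_by_agent.items():
        if know != "explicit":
            continue
        named = set(named_shapes_by_agent.get(aid, ()))
        if not named:
            continue
        shape_vars = per_shape.loc[aid]
        unnamed = set(shape_vars.index) - named
        if not unnamed:
            continue
        named_vars.append(float(shape_vars.loc[sorted(named & set(shape_vars.index))].mean()))
        unnamed_vars.append(float(shape_vars.loc[sorted(unnamed)].mean()))
        agents.append(aid)

    result: Dict = {"anova": anova, "n_named_contrast": len(agents)}
    if len(agents) >= 3:
        result["named_vs_unnamed"] = _paired_t(
            np.array(unnamed_vars), np.array(named_vars),
            name="unnamed_minus_named_variance")
    return result


def implicit_variance_devaluation_correlation(
    auction: pd.DataFrame,
    implicit_agents: Sequence[int],
    cooks_threshold: Optional[float] = None,
) -> Dict:
    """Among implicit learners, correlate a compound bidding-variance measure
    (mean per-shape bid-level variance over the four extreme-value shapes,
    levels 1 and 4) with the devaluation score, after dropping
    high-influence points by Cook's distance (> 4/N by default)."""
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import OLSInfluence

    sub = auction[auction["agent_id"].isin(implicit_agents)]
    if sub["agent_id"].nunique() < 10:
        raise ValueError("need at least 10 implicit learners")
    extreme = sub[sub["value_level"].isin([1, 4])]
    compound = (
        extreme.groupby(["agent_id", "shape_id"])["bid_level"].var()
        .groupby("agent_id").mean()
    )
    scores = devaluation_scores(sub)
    df = pd.DataFrame({"compound_variance": compound,
                       "devaluation_score": scores}).dropna()

    X = sm.add_constant(df["compound_variance"].to_numpy())
    fit = sm.OLS(df["devaluation_score"].to_numpy(), X).fit()
    cooks = OLSInfluence(fit).cooks_distance[0]
    thr = cooks_threshold if cooks_threshold is not None else 4.0 / len(df)
    keep = cooks <= thr
    retained = df[keep]
    if len(retained) < 3:
        raise ValueError("Cook's-distance filter removed too many points")
    r, p = stats.pearsonr(retained["compound_variance"],
                          retained["devaluation_score"])
    return {
        "result": StatResult(
            name="implicit_variance_devaluation", statistic="r_pearson",
            value=float(r), n=len(retained), p=float(p), effect_size=float(r),
            effect_size_name="r", effect_size_formula="Pearson r"),
        "n_removed": int((~keep).sum()),
        "removed_agents": retained.index.symmetric_difference(df.index).tolist(),
        "data": df.assign(retained=keep),
    }
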