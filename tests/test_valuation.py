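"""Valuation-phase dependent variables and the statistical machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st

from devalsim.agents import SimulatedDebrief
from devalsim.valuation import (
    bid_cell_summaries,
    bid_to_level,
    classify_knowledge,
    devaluation_scores,
    implicit_variance_devaluation_correlation,
    iqr_outlier_filter,
    mann_whitney_u,
    mixed_anova,
    r_from_z,
    wilcoxon_signed_rank,
    within_subjects_pair_analysis,
)
from _oracles import mann_whitney_exact_p, mixed_anova_cell_means, wilcoxon_exact_p

SET1 = (34, 68, 102, 136, 170, 204)
SET5 = (54, 108, 162, 216, 270, 324)


class TestBidToLevel:
    def test_highest_amount_is_level_6(self):
        assert bid_to_level(204, SET1) == 6

    def test_lowest_amount_is_level_1(self):
        assert bid_to_level(54, SET5) == 1

    def test_unknown_amount_rejected(self):
        with pytest.raises(ValueError):
            bid_to_level(100, SET1)

    def test_non_increasing_set_rejected(self):
        with pytest.raises(ValueError):
            bid_to_level(34, (34, 34, 102, 136, 170, 204))


class TestClassifyKnowledge:
    levels = {"square": 4, "circle": 1}

    def test_accurate_naming_is_explicit(self):
        d = SimulatedDebrief(True, [("square", 4)], False)
        assert classify_knowledge(d, self.levels) == "explicit"

    def test_no_feeling_is_implicit(self):
        d = SimulatedDebrief(False, [], False)
        assert classify_knowledge(d, self.levels) == "implicit"

    def test_wrong_relative_value_is_implicit(self):
        d = SimulatedDebrief(True, [("square", 1)], False)
        assert classify_knowledge(d, self.levels) == "implicit"


def make_auction(levels_by_shape, n_bids=10, agent_id=0):
    """Auction log from a {(shape, stop_paired, value_level): bid levels}
    description."""
    rows = []
    for (shape, stop, vlevel), bids in levels_by_shape.items():
        bids = np.resize(bids, n_bids)
        for b in bids:
            rows.append(dict(agent_id=agent_id, shape_id=shape,
                             stop_paired=stop, value_level=vlevel,
                             bid_level=float(b), bid_set_id=1))
    return pd.DataFrame(rows)


def balanced_auction(agent_id, go_levels, stop_levels):
    spec = {}
    for v in (1, 2, 3, 4):
        spec[(f"go{v}", False, v)] = go_levels
        spec[(f"stop{v}", True, v)] = stop_levels
    return make_auction(spec, agent_id=agent_id)


class TestDevaluationScores:
    def test_identical_bids_score_zero(self):
        df = balanced_auction(0, [3], [3])
        assert devaluation_scores(df).iloc[0] == 0.0

    def test_unit_gap_scores_one(self):
        df = balanced_auction(0, [4], [3])
        assert devaluation_scores(df).iloc[0] == 1.0

    def test_missing_shape_coverage_rejected(self):
        df = balanced_auction(0, [4], [3])
        with pytest.raises(ValueError):
            devaluation_scores(df[df.shape_id != "go2"])

    def test_shuffled_stop_labels_symmetric_about_zero(self, full_cohort, rng):
        """Permuting which shape of each value pair is called 'stop-paired'
        makes the score distribution symmetric around zero."""
        auction = full_cohort.auction
        means = []
        for _ in range(30):
            flip = {aid: rng.random() < 0.5 for aid in auction.agent_id.unique()}
            flipped = auction.copy()
            do_flip = flipped.agent_id.map(flip)
            flipped["stop_paired"] = flipped.stop_paired ^ do_flip
            means.append(devaluation_scores(flipped).mean())
        assert abs(np.mean(means)) < 0.05


class TestIqrOutlierFilter:
    def test_all_equal_removes_nothing(self):
        s = pd.Series([2.0] * 10)
        kept, removed = iqr_outlier_filter(s, pd.Series(["a"] * 10))
        assert len(kept) == 10 and removed.empty

    def test_gross_outlier_removed_within_its_group(self):
        s = pd.Series([0, 0.1, -0.1, 0.2, -0.2, 9.0, 0, 0.1, -0.1, 0.2])
        groups = pd.Series(["a"] * 6 + ["b"] * 4)
        kept, removed = iqr_outlier_filter(s, groups)
        assert removed.index.tolist() == [5]

    def test_normal_sample_rarely_flagged(self, rng):
        s = pd.Series(rng.normal(0, 1, 43))
        kept, removed = iqr_outlier_filter(s, pd.Series(["g"] * 43))
        assert len(removed) <= 3  # theoretical Tukey-fence rate ~0.7%/tail

    def test_small_group_skipped_with_warning(self):
        s = pd.Series([0.0, 1.0, 100.0])
        with pytest.warns(UserWarning):
            kept, _ = iqr_outlier_filter(s, pd.Series(["a"] * 3))
        assert len(kept) == 3


def random_balanced_dataset(rng, n_per_group=4, groups=2, J=2, K=4):
    rows = []
    for gi in range(groups):
        for s in range(n_per_group):
            sid = f"g{gi}s{s}"
            for j in range(J):
                for k in range(K):
                    rows.append((sid, f"grp{gi}", j, k, rng.normal()))
    return pd.DataFrame(rows, columns=["subject", "group", "w1", "w2", "dv"])


class TestMixedAnova:
    def test_df_pattern_for_59_subjects(self, rng):
        """22 + 37 subjects, 2x4 within cells: within error dfs are 57 and
        3 x 57 = 171."""
        rows = []
        for gi, n in enumerate((22, 37)):
            for s in range(n):
                for j in range(2):
                    for k in range(4):
                        rows.append((f"g{gi}s{s}", f"grp{gi}", j, k, rng.normal()))
        df = pd.DataFrame(rows, columns=["subject", "group", "w1", "w2", "dv"])
        res = mixed_anova(df, dv="dv", subject="subject", within=["w1", "w2"],
                          between="group").set_index("effect")
        assert res.loc["w1", ["df", "df_error"]].tolist() == [1, 57]
        assert res.loc["w2", ["df", "df_error"]].tolist() == [3, 171]
        assert res.loc["group", ["df", "df_error"]].tolist() == [1, 57]
        assert res.loc["group:w1", "df_error"] == 57

    def test_location_invariance(self, rng):
        df = random_balanced_dataset(rng)
        res1 = mixed_anova(df, dv="dv", subject="subject", within=["w1", "w2"],
                           between="group")
        df2 = df.assign(dv=df.dv + 17.3)
        res2 = mixed_anova(df2, dv="dv", subject="subject", within=["w1", "w2"],
                          between="group")
        np.testing.assert_allclose(res1.F, res2.F, rtol=1e-9)

    def test_matches_cell_means_oracle(self, rng):
        """F ratios and dfs agree with an independent textbook partition on
        random balanced datasets."""
        name_map = {"group": "G", "w1": "J", "group:w1": "GJ", "w2": "K",
                    "group:w2": "GK", "w1:w2": "JK", "group:w1:w2": "GJK"}
        for _ in range(5):
            df = random_balanced_dataset(rng, n_per_group=rng.integers(3, 6))
            res = mixed_anova(df, dv="dv", subject="subject",
                              within=["w1", "w2"], between="group").set_index("effect")
            oracle = mixed_anova_cell_means(df)
            for eff, key in name_map.items():
                ss_e, ss_err, d1, d2 = oracle[key]
                assert res.loc[eff, "df"] == d1
                assert res.loc[eff, "df_error"] == d2
                np.testing.assert_allclose(res.loc[eff, "ss_effect"], ss_e,
                                           rtol=1e-8, atol=1e-12)
                np.testing.assert_allclose(res.loc[eff, "ss_error"], ss_err,
                                           rtol=1e-8, atol=1e-12)

    def test_within_only_design(self, rng):
        """Single-group (fully within) ANOVA: VALUE error df = 3(N-1)."""
        df = random_balanced_dataset(rng, n_per_group=43, groups=1)
        res = mixed_anova(df, dv="dv", subject="subject",
                          within=["w1", "w2"]).set_index("effect")
        assert res.loc["w2", "df_error"] == 126
        assert "group" not in res.index

    def test_missing_cells_rejected(self, rng):
        df = random_balanced_dataset(rng)
        df = df[~((df.subject == "g0s0") & (df.w2 == 3))]
        with pytest.raises(ValueError):
            mixed_anova(df, dv="dv", subject="subject", within=["w1", "w2"],
                        between="group")

    def test_parametric_p_close_to_sign_flip_permutation(self, rng):
        """On a small dataset, the parametric p for the within STOPPING-like
        factor is close to a 10,000-draw sign-flip permutation p."""
        df = random_balanced_dataset(rng, n_per_group=3, J=2, K=4)
        df.loc[df.w1 == 0, "dv"] += 0.8  # moderate within effect
        res = mixed_anova(df, dv="dv", subject="subject", within=["w1", "w2"],
                          between="group").set_index("effect")
        p_param = res.loc["w1", "p"]

        # per-subject w1 difference scores; flipping the two within levels
        # of a subject negates its score
        d = (df[df.w1 == 0].groupby(["subject", "group"]).dv.mean()
             - df[df.w1 == 1].groupby(["subject", "group"]).dv.mean())
        d = d.reset_index()
        groups = d.group.to_numpy()
        vals = d.dv.to_numpy()
        glabels = np.unique(groups)
        n_g = np.array([(groups == g).sum() for g in glabels])
        hfac = len(glabels) ** 2 / (1.0 / n_g).sum()

        def stop_F(v):
            gm = np.array([v[groups == g].mean() for g in glabels])
            ss_eff = gm.mean() ** 2 * hfac
            resid = sum(((v[groups == g] - v[groups == g].mean()) ** 2).sum()
                        for g in glabels)
            # z-scores are d/sqrt(2) under the orthonormal contrast; the
            # scale cancels in the F ratio
            return ss_eff / (resid / (len(v) - len(glabels)))

        f_obs = stop_F(vals)
        flips = rng.random((10_000, len(vals))) < 0.5
        f_perm = np.array([stop_F(np.where(f, -vals, vals)) for f in flips])
        p_perm = (f_perm >= f_obs - 1e-12).mean()
        assert abs(p_param - p_perm) < 0.05


class TestNonparametrics:
    def test_r_from_z_reproduces_reported_effect_sizes(self):
        assert r_from_z(2.36, 65) == pytest.approx(0.292, abs=1e-3)
        assert r_from_z(2.2, 65) == pytest.approx(0.273, abs=1e-3)

    def test_wilcoxon_five_positive_differences(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5])
        assert res.p == pytest.approx(0.0625)

    def test_wilcoxon_sign_flip_negates_z(self):
        d = [1.2, -0.5, 2.0, 0.7, -1.1, 0.3]
        res = wilcoxon_signed_rank(d)
        flipped = wilcoxon_signed_rank([-x for x in d])
        assert flipped.value == pytest.approx(-res.value)
        assert flipped.p == pytest.approx(res.p)

    def test_wilcoxon_all_zero_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0])

    def test_mann_whitney_tiny_case(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.value == 0.0
        assert res.p == pytest.approx(1 / 3)

    def test_mann_whitney_identical_groups(self):
        res = mann_whitney_u([1, 2, 3, 4.5], [1, 2, 3, 4.5])
        assert abs(res.df) < 1e-9  # Z ~ 0
        assert res.p > 0.9

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-40, 40), min_size=4, max_size=8, unique=True))
    def test_wilcoxon_matches_enumeration(self, diffs):
        """Exact signed-rank p equals full 2^n sign enumeration for tie-free
        samples up to n = 8."""
        d = [x + 0.5 for x in diffs]  # avoid zeros, keep uniqueness
        assume(len({abs(v) for v in d}) == len(d))  # exact path needs tie-free |d|
        assert wilcoxon_signed_rank(d).p == pytest.approx(wilcoxon_exact_p(d))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 100), min_size=2, max_size=8, unique=True),
        st.integers(2, 6),
    )
    def test_mann_whitney_matches_enumeration(self, pool, split):
        a = [x + 0.25 for x in pool[:split]]
        b = [x + 0.75 for x in pool[split:]]
        if not a or not b:
            return
        assert mann_whitney_u(a, b).p == pytest.approx(mann_whitney_exact_p(a, b))


class TestWithinSubjectsPairs:
    def _named(self, *shapes):
        return {0: list(shapes)}

    def test_all_pairs_one_condition_excluded(self):
        df = balanced_auction(0, [4], [3])
        with pytest.raises(ValueError):
            within_subjects_pair_analysis(
                df, self._named("go1", "go2", "go3", "go4"), [0])

    def test_equal_levels_give_zero_percent(self):
        frames = [balanced_auction(aid, [4], [4]) for aid in range(6)]
        df = pd.concat(frames)
        named = {aid: ["go1"] for aid in range(6)}
        res = within_subjects_pair_analysis(df, named, list(range(6)))
        assert res["explicit_pair_mean_pct"] == 0.0
        assert res["implicit_pair_mean_pct"] == 0.0

    def test_effect_restricted_to_named_pairs_is_recovered(self, rng):
        """When only named-value pairs carry devaluation, the explicit-pair
        percentage exceeds the implicit-pair percentage."""
        frames, named = [], {}
        for aid in range(12):
            spec = {}
            for v in (1, 2, 3, 4):
                base = 1 + v * 0.9
                deval = 0.8 if v == 4 else 0.0  # only the named pair devalues
                spec[(f"go{v}", False, v)] = np.clip(
                    base + rng.normal(0, 0.3, 10), 1, 6)
                spec[(f"stop{v}", True, v)] = np.clip(
                    base - deval + rng.normal(0, 0.3, 10), 1, 6)
            frames.append(make_auction(spec, agent_id=aid))
            named[aid] = ["go4"]
        df = pd.concat(frames)
        res = within_subjects_pair_analysis(df, named, list(range(12)))
        assert res["n"] == 12
        assert res["explicit_pair_mean_pct"] > res["implicit_pair_mean_pct"]
        assert res["explicit_vs_implicit"].p < 0.05

    def test_direction_on_simulated_cohort(self, full_report):
        ws = full_report["within_subjects_analysis"]
        assert ws["explicit_pair_mean_pct"] > ws["implicit_pair_mean_pct"]


class TestBiddingVariance:
    def test_constant_bids_have_zero_variance(self):
        df = balanced_auction(0, [3], [2])
        cells = bid_cell_summaries(df)
        assert (cells.bid_level_variance == 0).all()

    def test_variance_anova_reports_knowledge_effect(self, full_report):
        anova = full_report["bidding_level_variance"]["anova"].set_index("effect")
        assert "knowledge" in anova.index
        assert anova.loc["knowledge", "df_error"] == (
            full_report["valuation_phase"]["n_analyzed"] - 2)

    def test_named_shapes_show_lower_variance(self, full_report):
        res = full_report["bidding_level_variance"].get("named_vs_unnamed")
        assert res is not None
        assert res.value > 0  # unnamed minus named variance is positive

    def test_explicit_variance_lower_on_cohort(self, full_cohort, full_report):
        knowledge = full_report["types_of_knowledge"]["knowledge"]
        per_agent = full_cohort.auction.groupby(
            ["agent_id", "shape_id"]).bid_level.var().groupby("agent_id").mean()
        expl = per_agent[[a for a in per_agent.index if knowledge.get(a) == "explicit"]]
        impl = per_agent[[a for a in per_agent.index if knowledge.get(a) == "implicit"]]
        assert expl.mean() < impl.mean()


class TestImplicitVarianceCorrelation:
    def _build(self, rng, n=30, couple=True):
        frames = []
        for aid in range(n):
            sd = rng.uniform(0.2, 1.4)
            deval = (1.4 - sd) * 0.5 if couple else 0.0
            spec = {}
            for v in (1, 2, 3, 4):
                base = 1 + v
                spec[(f"go{v}", False, v)] = np.clip(
                    base + rng.normal(0, sd, 10), 1, 6)
                spec[(f"stop{v}", True, v)] = np.clip(
                    base - deval + rng.normal(0, sd, 10), 1, 6)
            frames.append(make_auction(spec, agent_id=aid))
        return pd.concat(frames)

    def test_coupled_noise_and_devaluation_yield_negative_r(self, rng):
        df = self._build(rng, couple=True)
        res = implicit_variance_devaluation_correlation(df, list(range(30)))
        assert res["result"].value < 0
        assert res["result"].p < 0.05

    def test_uncoupled_agents_give_null_r(self, rng):
        rs = []
        for _ in range(40):
            df = self._build(rng, n=20, couple=False)
            res = implicit_variance_devaluation_correlation(df, list(range(20)))
            rs.append(res["result"].value)
        assert abs(np.mean(rs)) < 0.1

    def test_high_leverage_outlier_removed(self, rng):
        df = self._build(rng, n=20, couple=False)
        # one agent with wildly out-of-range compound variance / score pairing
        spec = {}
        for v in (1, 2, 3, 4):
            spec[(f"go{v}", False, v)] = [1, 6] * 5    # maximal variance
            spec[(f"stop{v}", True, v)] = [1.0] * 10
        df = pd.concat([df, make_auction(spec, agent_id=99)])
        res = implicit_variance_devaluation_correlation(df, list(range(20)) + [99])
        assert res["n_removed"] >= 1
        assert 99 not in res["data"][res["data"].retained].index

    def test_requires_ten_implicit_learners(self, rng):
        df = self._build(rng, n=5)
        with pytest.raises(ValueError):
            implicit_variance_devaluation_correlation(df, list(range(5)))
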