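"""Scalar statistics layer: ANOVAs against explicit sum-of-squares
oracles, effect sizes, corrections, correlation and reliability."""

import numpy as np
import pytest
from scipy import stats

from pupilwalk.aggregate_stats import (
    accuracy_vs_chance,
    cohens_dz,
    mixed_anova_2xk,
    paired_tests_with_corrections,
    partial_eta_sq,
    pearson_with_ci,
    reliability,
    rm_anova_oneway,
)


def rm_anova_ss_oracle(values):
    """Direct within-subject sum-of-squares decomposition."""
    n, k = values.shape
    grand = values.mean()
    ss_cond = n * ((values.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((values.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((values - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    return (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))


def splitplot_interaction_oracle(values, groups):
    """Explicit split-plot decomposition; returns the interaction F."""
    n, k = values.shape
    grand = values.mean()
    labels = np.unique(groups)
    ss_inter = 0.0
    for g in labels:
        sub = values[groups == g]
        for j in range(k):
            cell = sub[:, j].mean()
            ss_inter += sub.shape[0] * (
                cell - sub.mean() - values[:, j].mean() + grand
            ) ** 2
    # within-subject error: total within-cells SS minus subject SS within groups
    ss_within_err = 0.0
    for g in labels:
        sub = values[groups == g]
        subj_means = sub.mean(axis=1)
        for j in range(k):
            cell_mean = sub[:, j].mean()
            ss_within_err += ((sub[:, j] - subj_means - cell_mean + sub.mean()) ** 2).sum()
    df_inter = (len(labels) - 1) * (k - 1)
    df_err = (n - len(labels)) * (k - 1)
    return (ss_inter / df_inter) / (ss_within_err / df_err)


class TestRmAnova:
    def test_matches_ss_oracle_on_toy_matrix(self):
        rng = np.random.default_rng(8)
        values = rng.normal(0, 1, (4, 3)) + np.array([0.0, 0.4, 0.9])
        res = rm_anova_oneway(values)
        assert res.F == pytest.approx(rm_anova_ss_oracle(values), rel=1e-9)

    def test_identical_conditions_give_zero_F(self):
        values = np.tile(np.random.default_rng(9).normal(size=(6, 1)), (1, 3))
        res = rm_anova_oneway(values)
        assert res.F == 0.0 and res.partial_eta_sq == 0.0

    def test_two_conditions_epsilon_is_one_and_F_equals_t_squared(self):
        rng = np.random.default_rng(10)
        values = rng.normal(0, 1, (12, 2)) + np.array([0.0, 0.5])
        res = rm_anova_oneway(values)
        t, p = stats.ttest_rel(values[:, 0], values[:, 1])
        assert res.gg_epsilon == 1.0
        assert res.F == pytest.approx(t**2, rel=1e-9)
        assert res.p_uncorrected == pytest.approx(p, rel=1e-9)

    def test_eta_sq_identity_with_reported_F(self):
        rng = np.random.default_rng(11)
        values = rng.normal(0, 1, (10, 3)) + np.array([0.0, 0.3, 0.7])
        res = rm_anova_oneway(values)
        assert res.partial_eta_sq == pytest.approx(
            partial_eta_sq(res.F, res.df_effect, res.df_error), rel=1e-9
        )

    def test_gg_epsilon_bounds_and_corrected_dfs(self):
        rng = np.random.default_rng(12)
        base = rng.normal(0, 1, (9, 1))
        values = np.hstack([base, base * 3 + rng.normal(0, 0.1, (9, 1)),
                            rng.normal(0, 2, (9, 1))])
        res = rm_anova_oneway(values)
        k = 3
        assert 1.0 / (k - 1) <= res.gg_epsilon <= 1.0
        assert res.df_effect_gg == pytest.approx(res.gg_epsilon * res.df_effect)

    def test_missing_cells_rejected(self):
        values = np.ones((5, 3))
        values[0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova_oneway(values)


class TestMixedAnova:
    def test_interaction_dfs_for_two_groups_of_24(self):
        rng = np.random.default_rng(13)
        values = rng.normal(0, 1, (48, 3))
        groups = np.repeat(["upright", "inverted"], 24)
        res = mixed_anova_2xk(values, groups)
        assert (res.df_effect, res.df_error) == (2.0, 92.0)

    def test_identical_group_profiles_zero_interaction(self):
        rng = np.random.default_rng(14)
        block = rng.normal(0, 1, (6, 3))
        values = np.vstack([block, block])
        groups = np.repeat(["a", "b"], 6)
        res = mixed_anova_2xk(values, groups)
        assert res.F == pytest.approx(0.0, abs=1e-9)

    def test_matches_splitplot_oracle(self):
        rng = np.random.default_rng(15)
        values = rng.normal(0, 1, (8, 2))
        values[4:, 1] += 1.0  # group-specific condition effect
        groups = np.repeat(["a", "b"], 4)
        res = mixed_anova_2xk(values, groups)
        assert res.F == pytest.approx(splitplot_interaction_oracle(values, groups), rel=1e-9)

    def test_subject_constant_invariance(self):
        rng = np.random.default_rng(16)
        values = rng.normal(0, 1, (10, 3))
        groups = np.repeat(["a", "b"], 5)
        res1 = mixed_anova_2xk(values, groups)
        res2 = mixed_anova_2xk(values + rng.normal(0, 5, (10, 1)), groups)
        assert res1.F == pytest.approx(res2.F, rel=1e-9)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="singleton"):
            mixed_anova_2xk(np.ones((3, 2)), ["a", "a", "b"])


class TestEffectSizes:
    @pytest.mark.parametrize(
        "t, n, expected",
        [(3.34, 24, 0.68), (2.73, 24, 0.56), (-2.43, 24, 0.50), (4.23, 24, 0.86), (0.0, 24, 0.0)],
    )
    def test_cohens_dz_reference_pairs(self, t, n, expected):
        assert round(cohens_dz(t, n), 2) == expected

    @pytest.mark.parametrize(
        "F, df1, df2, expected",
        [(12.0, 2, 46, 0.34), (8.92, 2, 46, 0.28), (4.53, 2, 92, 0.09), (0.0, 2, 46, 0.0)],
    )
    def test_partial_eta_sq_reference_pairs(self, F, df1, df2, expected):
        assert round(partial_eta_sq(F, df1, df2), 2) == expected


class TestPairedCorrections:
    def test_holm_step_down_hand_oracle(self):
        """From t = {2.73, -2.43, 3.34} at df 23 the Holm-adjusted ps are
        {0.024, 0.024, 0.009} and Bonferroni for t = 2.73 is 0.036."""
        rng = np.random.default_rng(20)
        n = 24
        base = rng.normal(0, 1.0, n)
        values = np.zeros((n, 4))
        # construct columns whose pairwise t against col 3 equal the targets
        for j, t_target in enumerate([2.73, -2.43, 3.34]):
            d = rng.normal(0, 1.0, n)
            d = (d - d.mean()) / d.std(ddof=1)  # mean 0, sd 1
            values[:, j] = base + d + t_target / np.sqrt(n)  # paired t = target
        values[:, 3] = base
        res = paired_tests_with_corrections(
            values, ["happy", "sad", "neutral", "ref"],
            [("happy", "ref"), ("sad", "ref"), ("neutral", "ref")],
        )
        assert [round(r.t, 2) for r in res] == [2.73, -2.43, 3.34]
        assert [round(r.p_holm, 3) for r in res] == [0.024, 0.024, 0.009]
        assert round(res[0].p_bonferroni, 3) == 0.036
        for r in res:
            assert r.p_holm >= r.p_uncorrected
            assert r.p_bonferroni >= r.p_holm

    def test_single_comparison_family_no_correction(self):
        rng = np.random.default_rng(21)
        values = rng.normal(0, 1, (10, 2)) + np.array([0.0, 0.8])
        (res,) = paired_tests_with_corrections(values, ["a", "b"], [("a", "b")])
        assert res.p_holm == pytest.approx(res.p_uncorrected)
        assert res.p_bonferroni == pytest.approx(res.p_uncorrected)

    def test_ci_contains_mean_difference(self):
        rng = np.random.default_rng(22)
        values = rng.normal(0, 1, (15, 2))
        (res,) = paired_tests_with_corrections(values, ["a", "b"], [("a", "b")])
        lo, hi = res.mean_diff_ci95
        assert lo < res.mean_diff < hi

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            paired_tests_with_corrections(np.ones((5, 2)), ["a", "b"], [])


class TestCorrelation:
    def test_fisher_ci_reference_values(self):
        """r = -0.47 at n = 24 gives the 95% CI [-0.73, -0.08]; r = -0.61
        gives [-0.81, -0.27] (Fisher z with 1.96/sqrt(n-3))."""
        for r_target, expected in [(-0.47, (-0.73, -0.08)), (-0.61, (-0.81, -0.27))]:
            x = np.linspace(-1, 1, 24)
            resid = np.sin(np.arange(24) * 2.7)
            resid -= np.polyval(np.polyfit(x, resid, 1), x)  # orthogonal to x
            y = r_target * x / x.std(ddof=0) + np.sqrt(1 - r_target**2) * resid / resid.std(ddof=0)
            res = pearson_with_ci(x, y)
            assert res.r == pytest.approx(r_target, abs=1e-12)
            assert res.df == 22
            assert tuple(round(c, 2) for c in res.ci95) == expected

    def test_zero_correlation_symmetric_ci(self):
        x = np.linspace(-1, 1, 24)
        y = np.abs(x) - np.abs(x).mean()  # exactly uncorrelated with x
        res = pearson_with_ci(x, y)
        assert res.r == pytest.approx(0.0, abs=1e-12)
        assert res.ci95[0] == pytest.approx(-res.ci95[1], abs=1e-12)

    def test_p_from_t_transform(self):
        rng = np.random.default_rng(23)
        x, y = rng.normal(size=(2, 30))
        res = pearson_with_ci(x, y)
        t = res.r * np.sqrt((res.n - 2) / (1 - res.r**2))
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t), res.n - 2), rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_with_ci(np.ones(10), np.arange(10.0))


class TestReliability:
    def test_perfect_reliability(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        res = reliability(x, x.copy())
        assert res.test_retest_r == pytest.approx(1.0)
        assert res.cronbach_alpha == pytest.approx(1.0)

    def test_equal_variance_closed_form(self):
        # equal variances with r = 0.5 -> alpha = 2r/(1+r) = 2/3
        rng = np.random.default_rng(24)
        a = rng.normal(0, 1, 2000)
        shared = a.copy()
        b = 0.5 * shared + np.sqrt(0.75) * rng.normal(0, 1, 2000)
        res = reliability(a, b)
        assert res.cronbach_alpha == pytest.approx(
            2 * res.test_retest_r / (1 + res.test_retest_r), abs=0.01
        )

    def test_toy_vectors_against_variance_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 4.0])
        res = reliability(a, b)
        expect = 2 * (1 - (np.var(a, ddof=1) + np.var(b, ddof=1)) / np.var(a + b, ddof=1))
        assert res.cronbach_alpha == pytest.approx(expect, rel=1e-12)
        assert res.cronbach_alpha == pytest.approx(12 / 13, rel=1e-12)


class TestAccuracy:
    def test_all_at_chance_gives_t_zero(self):
        res = accuracy_vs_chance([0.5, 0.5, 0.5])
        assert res.t == 0.0 and res.p == 1.0

    def test_sem_hand_oracle(self):
        acc = [0.8, 0.9, 0.8]
        res = accuracy_vs_chance(acc)
        assert res.sem == pytest.approx(np.std(acc, ddof=1) / np.sqrt(3), rel=1e-12)
        assert res.mean == pytest.approx(np.mean(acc))

    def test_configurable_chance_level(self):
        res = accuracy_vs_chance([0.4, 0.3, 0.35], chance=1 / 3)
        t, p = stats.ttest_1samp([0.4, 0.3, 0.35], 1 / 3)
        assert res.t == pytest.approx(t) and res.p == pytest.approx(p)
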