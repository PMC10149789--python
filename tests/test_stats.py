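"""Inference toolbox: t/g, Pearson, BH, BCa bootstrap, CI-inversion
p-values, bisquare IRLS regression, f²."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aptemporal.stats import (
    BootstrapConfig,
    _bca_interval,
    bca_ci,
    bh_adjust,
    cohens_f2,
    hedges_g,
    p_from_ci_inversion,
    pearson_r,
    robust_lm,
    student_t,
)


class TestStudentT:
    def test_identical_samples(self):
        with pytest.raises(ValueError):
            student_t([1, 1, 1], [1, 1, 1])  # zero pooled variance
        t, df, diff = student_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and diff == 0.0

    def test_hand_computation(self):
        t, df, diff = student_t([1, 2, 3], [2, 3, 4])
        assert df == 4
        assert t == pytest.approx(-np.sqrt(1.5))
        assert diff == -1.0

    def test_published_df(self):
        rng = np.random.default_rng(0)
        t, df, _ = student_t(rng.normal(size=9), rng.normal(size=10))
        assert df == 17

    def test_agrees_with_scipy(self):
        from scipy import stats as sps

        rng = np.random.default_rng(1)
        x, y = rng.normal(size=12), rng.normal(0.5, 1.2, size=9)
        t, df, _ = student_t(x, y)
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(ref.statistic)


class TestHedgesG:
    def test_zero_effect(self):
        assert hedges_g(0.0, 9, 10) == 0.0

    @pytest.mark.parametrize(
        "t,n1,n2,expected,tol",
        [
            # published value 0.099 printed from an unrounded t; the rounded
            # t = -0.229 reproduces it to ~1e-3
            (-0.229, 9, 10, 0.099, 2e-3),
            (0.042, 9, 10, 0.018, 5e-4),
        ],
    )
    def test_published_values(self, t, n1, n2, expected, tol):
        assert hedges_g(t, n1, n2) == pytest.approx(expected, abs=tol)

    def test_magnitude_convention(self):
        assert hedges_g(-2.0, 9, 10) == hedges_g(2.0, 9, 10) > 0


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computation(self):
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_ties_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_order_preserved(self):
        p = [0.04, 0.001, 0.3]
        adj = bh_adjust(p)
        assert np.argmin(adj) == 1 and np.argmax(adj) == 2

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_matches_statsmodels_and_idempotent(self, pvals):
        from statsmodels.stats.multitest import multipletests

        ours = bh_adjust(pvals)
        _, ref, _, _ = multipletests(pvals, method="fdr_bh")
        assert np.allclose(ours, ref)
        assert np.allclose(bh_adjust(ours), np.minimum(ours, 1.0)) or np.all(
            bh_adjust(ours) <= 1.0
        )
        # nondecreasing in the sorted order
        order = np.argsort(pvals)
        assert np.all(np.diff(np.asarray(ours)[order]) >= -1e-12)


class TestBcaCI:
    def test_constant_data_point_interval(self):
        with pytest.warns(UserWarning):
            lo, hi = bca_ci(np.mean, np.full(10, 3.0), BootstrapConfig(B=200, seed=0))
        assert lo == hi == 3.0

    def test_reduces_to_percentile_when_unbiased_symmetric(self):
        """With z0 = 0 and a = 0 the BCa endpoints are the plain
        percentile-interval endpoints."""
        reps = np.random.default_rng(0).normal(size=4000)
        lo, hi = _bca_interval(reps, z0=0.0, a=0.0, level=0.95)
        assert lo == pytest.approx(np.quantile(reps, 0.025))
        assert hi == pytest.approx(np.quantile(reps, 0.975))

    def test_deterministic_under_seed(self):
        data = np.random.default_rng(5).normal(size=25)
        cfg = BootstrapConfig(B=500, seed=9)
        assert bca_ci(np.mean, data, cfg) == bca_ci(np.mean, data, cfg)

    def test_contains_point_estimate_for_mean(self):
        data = np.random.default_rng(2).normal(size=30)
        lo, hi = bca_ci(np.mean, data, BootstrapConfig(B=1000, seed=3))
        assert lo < data.mean() < hi

    def test_two_sample_statistic(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(2, 1, 15), rng.normal(0, 1, 15)
        stat = lambda a, b: float(np.mean(a) - np.mean(b))
        lo, hi = bca_ci(stat, (x, y), BootstrapConfig(B=1000, seed=5))
        assert lo > 0  # clearly separated means


class TestCIInversion:
    def test_null_at_point_estimate(self):
        data = np.random.default_rng(1).normal(size=25)
        p = p_from_ci_inversion(
            np.mean, data, float(np.mean(data)), BootstrapConfig(B=500, seed=2)
        )
        assert p > 0.5

    def test_floor_at_2_over_B(self):
        data = np.random.default_rng(1).normal(10, 0.1, 25)
        with pytest.warns(UserWarning):
            p = p_from_ci_inversion(np.mean, data, 0.0, BootstrapConfig(B=500, seed=2))
        assert p == pytest.approx(2 / 500)

    @pytest.mark.parametrize("seed", range(12))
    def test_consistent_with_ci(self, seed):
        """p < 0.05 exactly when the 95% BCa interval excludes the null."""
        rng = np.random.default_rng(seed)
        data = rng.normal(rng.uniform(-0.6, 0.6), 1.0, 15)
        cfg = BootstrapConfig(B=400, seed=seed)
        lo, hi = bca_ci(np.mean, data, cfg)
        p = p_from_ci_inversion(np.mean, data, 0.0, cfg)
        assert (p < 0.05) == (lo > 0 or hi < 0)


class TestRobustLM:
    def test_exact_line(self):
        x = np.linspace(0, 10, 20)
        fit = robust_lm(2 * x + 1, x)
        assert fit.params == pytest.approx([1.0, 2.0])
        assert fit.r2 == 1.0

    def test_outlier_resistance(self):
        x = np.linspace(0, 10, 20)
        y = 2 * x + 1 + np.random.default_rng(2).normal(0, 0.2, 20)
        y[19] -= 60.0
        fit = robust_lm(y, x)
        ols_slope = np.polyfit(x, y, 1)[0]
        assert abs(fit.params[1] - 2.0) < 0.1
        assert abs(ols_slope - 2.0) > 0.5

    def test_agrees_with_ols_on_clean_data(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 2))
        y = 1.0 + X @ [0.5, -1.2] + rng.normal(0, 0.02, 200)
        fit = robust_lm(y, X)
        D = np.column_stack([np.ones(200), X])
        ols = np.linalg.lstsq(D, y, rcond=None)[0]
        assert np.max(np.abs((fit.params - ols) / ols)) < 1e-3

    def test_cross_check_against_statsmodels_rlm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 2))
        y = 2.0 + X @ [1.5, -0.7] + rng.standard_t(3, 60)
        fit = robust_lm(y, X)
        ref = sm.RLM(y, sm.add_constant(X), M=sm.robust.norms.TukeyBiweight()).fit()
        # different scale-updating schemes, so coefficients agree loosely
        assert np.allclose(fit.params, ref.params, atol=0.15)

    def test_effect_size_identities(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=15)
        y = 1 + 0.8 * x + rng.normal(0, 1, 15)
        fit = robust_lm(y, x)
        assert fit.f2 == pytest.approx(fit.r2 / (1 - fit.r2))
        assert fit.adj_r2 <= fit.r2
        # standardized slope equals b * sd(x)/sd(y)
        assert fit.beta_std[1] == pytest.approx(
            fit.params[1] * np.std(x, ddof=1) / np.std(y, ddof=1)
        )
        assert np.isnan(fit.beta_std[0])

    def test_rank_deficiency_and_size_errors(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError):
            robust_lm(x, np.column_stack([x, 2 * x]))
        with pytest.raises(ValueError):
            robust_lm([1.0, 2.0], [[1.0], [2.0]])


class TestCohensF2:
    @pytest.mark.parametrize(
        "r2,expected",
        [
            (0.0, 0.0),
            (0.300, 0.429),
            (0.315, 0.460),
            (0.428, 0.748),
            (0.442, 0.792),
            (0.680, 2.125),
            (0.659, 1.933),
            (0.452, 0.825),
            (0.479, 0.919),
        ],
    )
    def test_published_variance_pairs(self, r2, expected):
        """Every published (variance %, f²) pair satisfies f² = R²/(1-R²)."""
        assert cohens_f2(r2) == pytest.approx(expected, abs=5e-4)

    def test_incremental_form(self):
        assert cohens_f2(0.5, 0.3) == pytest.approx(0.4)

    def test_domain(self):
        with pytest.raises(ValueError):
            cohens_f2(1.0)
        with pytest.raises(ValueError):
            cohens_f2(-0.1)
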