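"""Loess trends with CIs, correlation brackets, and feasible GLS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photodose.trends import (
    bracket_for_r,
    ci_overlap,
    fit_gls_cs,
    loess_fit,
    pearson_r_with_test,
    select_model,
    significance_bracket,
)


def simulate_cs_data(rng, n_groups=20, group_size=8, beta=(1.0, 0.02),
                     rho=0.5, sigma=0.1):
    """CS data: shared group effect carries a fraction rho of the variance."""
    rows = n_groups * group_size
    x = rng.uniform(0.0, 25.0, rows)
    groups = np.repeat(np.arange(n_groups), group_size)
    b = rng.normal(0.0, np.sqrt(rho) * sigma, n_groups)
    e = rng.normal(0.0, np.sqrt(1.0 - rho) * sigma, rows)
    y = beta[0] + beta[1] * x + b[groups] + e
    X = np.column_stack([np.ones(rows), x])
    return y, X, groups


class TestLoess:
    def test_noiseless_quadratic_reproduced_exactly(self):
        x = np.linspace(0.0, 10.0, 30)
        y = 1.0 + 0.5 * x - 0.2 * x ** 2
        fit = loess_fit(x, y, span=1.0, degree=2, grid=x)
        np.testing.assert_allclose(fit.fitted, y, atol=1e-8)

    def test_constant_series_has_degenerate_interval(self):
        x = np.linspace(0.0, 10.0, 20)
        fit = loess_fit(x, np.full(20, 3.0), span=1.0, grid=x[2:18])
        np.testing.assert_allclose(fit.fitted, 3.0, atol=1e-10)
        np.testing.assert_allclose(fit.se, 0.0, atol=1e-10)
        np.testing.assert_allclose(fit.ci_lower, fit.ci_upper, atol=1e-9)

    def test_ci_bounds_bracket_the_fit(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(0, 100, 60))
        y = 0.01 * x + rng.normal(0, 0.2, 60)
        fit = loess_fit(x, y, span=0.7)
        assert np.all(fit.ci_lower <= fit.fitted)
        assert np.all(fit.fitted <= fit.ci_upper)

    def test_sine_recovered_from_noise(self):
        rng = np.random.default_rng(123)
        rmses = []
        for _ in range(50):
            x = np.sort(rng.uniform(0.0, 125.0, 200))
            truth = np.sin(x / 20.0)
            y = truth + rng.normal(0.0, 0.05, 200)
            lo, hi = np.quantile(x, [0.1, 0.9])
            grid = np.linspace(lo, hi, 40)
            fit = loess_fit(x, y, span=0.5, grid=grid)
            rmses.append(np.sqrt(np.mean((fit.fitted - np.sin(grid / 20.0)) ** 2)))
        assert np.mean(rmses) < 0.05

    def test_span_too_small_for_local_degree(self):
        x = np.linspace(0, 10, 20)
        with pytest.raises(ValueError, match="increase the span"):
            loess_fit(x, x, span=0.1, degree=2, grid=np.array([5.0]))


class TestCiOverlap:
    @staticmethod
    def _fit_like(grid, lower, upper):
        from photodose.trends import LoessFit

        mid = (lower + upper) / 2.0
        return LoessFit(grid=grid, fitted=mid, se=(upper - lower) / 4.0,
                        ci_lower=lower, ci_upper=upper, span=1.0, degree=2,
                        df_resid=10.0, sigma=1.0)

    def test_identical_fits_overlap_everywhere(self):
        grid = np.arange(100.0, 110.0)
        a = self._fit_like(grid, np.zeros(10), np.ones(10))
        report = ci_overlap(a, a)
        assert not report["non_overlap"].any()
        assert report["intervals"] == []

    def test_disjoint_bands_never_overlap(self):
        grid = np.arange(100.0, 110.0)
        a = self._fit_like(grid, np.zeros(10), np.ones(10))
        b = self._fit_like(grid, np.full(10, 2.0), np.full(10, 3.0))
        report = ci_overlap(a, b)
        assert report["non_overlap"].all()
        assert report["intervals"] == [(100.0, 109.0)]

    def test_symmetry(self):
        grid = np.arange(0.0, 20.0)
        rng = np.random.default_rng(3)
        lo1 = rng.normal(0, 1, 20)
        lo2 = rng.normal(1, 1, 20)
        a = self._fit_like(grid, lo1, lo1 + 1.0)
        b = self._fit_like(grid, lo2, lo2 + 1.0)
        ab, ba = ci_overlap(a, b), ci_overlap(b, a)
        np.testing.assert_array_equal(ab["non_overlap"], ba["non_overlap"])
        assert ab["intervals"] == ba["intervals"]

    def test_mismatched_grids_rejected(self):
        a = self._fit_like(np.arange(0.0, 10.0), np.zeros(10), np.ones(10))
        b = self._fit_like(np.arange(5.0, 15.0), np.zeros(10), np.ones(10))
        with pytest.raises(ValueError, match="same grid"):
            ci_overlap(a, b)


class TestPearson:
    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_covariance_ratio(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        x = rng.normal(size=n)
        y = rng.normal(size=n) + 0.3 * x
        res = pearson_r_with_test(x, y)
        brute = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert res.r == pytest.approx(brute, abs=1e-12)

    def test_bracket_threshold_edges(self):
        # strict < 0.05 for one star; ≤ for the others
        assert significance_bracket(0.05) == "ns"
        assert significance_bracket(0.0499) == "*"
        assert significance_bracket(0.0101) == "*"
        assert significance_bracket(0.01) == "**"
        assert significance_bracket(0.00101) == "**"
        assert significance_bracket(0.001) == "***"

    def test_published_style_brackets_at_n16(self):
        assert bracket_for_r(0.63, 16) == "**"
        assert bracket_for_r(0.50, 16) == "*"

    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = pearson_r_with_test(x, 2.0 * x + 1.0)
        assert res.r == 1.0
        assert res.p == 0.0

    def test_zero_variance_gives_null(self):
        res = pearson_r_with_test(np.ones(5), np.arange(5.0))
        assert res.r is None
        assert res.reason == "zero variance"


class TestGls:
    def test_independence_structure_equals_ols(self):
        rng = np.random.default_rng(1)
        y, X, groups = simulate_cs_data(rng, rho=0.0)
        fit = fit_gls_cs(y, X, groups, correlation="none",
                         variance="homoscedastic")
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.params, ols, atol=1e-6)
        assert fit.rho == 0.0

    def test_parameter_recovery_under_cs(self):
        rng = np.random.default_rng(2)
        betas, rhos = [], []
        for _ in range(50):
            y, X, groups = simulate_cs_data(rng, rho=0.5)
            fit = fit_gls_cs(y, X, groups, variance="homoscedastic")
            betas.append(fit.params[1])
            rhos.append(fit.rho)
        assert np.mean(betas) == pytest.approx(0.02, rel=0.05)
        assert abs(np.mean(rhos) - 0.5) < 0.1

    def test_loglik_path_is_nondecreasing(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            y, X, groups = simulate_cs_data(rng, rho=0.4)
            fit = fit_gls_cs(y, X, groups, variance="homoscedastic")
            assert np.all(np.diff(fit.loglik_path) >= -1e-9)

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(4)
        y, X, groups = simulate_cs_data(rng)
        X_dup = np.column_stack([X, X[:, 1]])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_gls_cs(y, X_dup, groups)

    def test_stratum_variances_recovered(self):
        rng = np.random.default_rng(5)
        n_groups, m = 40, 6
        groups = np.repeat(np.arange(n_groups), m)
        strata = np.where(groups < n_groups // 2, "a", "b")
        x = rng.uniform(0, 25, n_groups * m)
        sd = np.where(strata == "a", 0.05, 0.25)
        y = 1.0 + 0.02 * x + rng.normal(0, sd)
        X = np.column_stack([np.ones(x.size), x])
        fit = fit_gls_cs(y, X, groups, strata, variance="by_stratum")
        assert fit.sigmas["a"] == pytest.approx(0.05, rel=0.3)
        assert fit.sigmas["b"] == pytest.approx(0.25, rel=0.3)

    def test_group_spanning_strata_rejected(self):
        y = np.arange(8.0)
        X = np.column_stack([np.ones(8), np.arange(8.0)])
        groups = np.repeat([0, 1], 4)
        strata = np.tile([0, 1], 4)
        with pytest.raises(ValueError, match="single stratum"):
            fit_gls_cs(y, X, groups, strata)

    def test_pseudo_r2_within_unit_interval(self):
        rng = np.random.default_rng(6)
        y, X, groups = simulate_cs_data(rng)
        fit = fit_gls_cs(y, X, groups, variance="homoscedastic")
        assert 0.0 <= fit.pseudo_r2 <= 1.0


class TestModelSelection:
    STRUCTURES = (("none", "homoscedastic"), ("cs", "homoscedastic"))

    def test_single_candidate_returned_unchanged(self):
        rng = np.random.default_rng(7)
        y, X, groups = simulate_cs_data(rng)
        best, fits = select_model(y, X, groups,
                                  structures=(("cs", "homoscedastic"),))
        assert best is fits[("cs", "homoscedastic")]

    def test_cs_structure_selected_when_planted(self):
        rng = np.random.default_rng(8)
        wins = 0
        for _ in range(30):
            y, X, groups = simulate_cs_data(rng, rho=0.6)
            best, _ = select_model(y, X, groups, structures=self.STRUCTURES)
            wins += best.correlation == "cs"
        assert wins >= 0.8 * 30

    def test_simplest_structure_selected_under_independence(self):
        rng = np.random.default_rng(9)
        wins = 0
        for _ in range(30):
            y, X, groups = simulate_cs_data(rng, n_groups=25, group_size=20,
                                            rho=0.0)
            best, _ = select_model(y, X, groups, structures=self.STRUCTURES)
            wins += best.correlation == "none"
        assert wins >= 0.8 * 30
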