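"""Trend battery: OLS trends, AR comparison, slope comparisons, partials."""

import numpy as np
import pytest
from scipy import stats

from grousepheno.trends import (gls_ar_compare, lagged_response,
                                log_ratio_trend, normalized_trend, ols_trend,
                                partial_regression, significance_label,
                                slope_difference_test, temp_response,
                                total_change)

YEARS = np.arange(1979, 2017)


class TestOlsTrend:
    def test_perfect_line(self):
        fit = ols_trend(YEARS, 2.0 * YEARS)
        assert fit.beta == pytest.approx(2.0)
        assert fit.r == pytest.approx(1.0)
        assert fit.se == pytest.approx(0.0, abs=1e-10)

    def test_constant_series_flat_with_undefined_r(self):
        fit = ols_trend(YEARS, np.full(38, 7.0))
        assert fit.beta == 0.0
        assert fit.delta == 0.0
        assert np.isnan(fit.r)

    def test_missing_years_dropped_pairwise(self):
        y = 0.1 * YEARS.astype(float)
        y[5:10] = np.nan
        fit = ols_trend(YEARS, y)
        assert fit.n == 33
        assert fit.beta == pytest.approx(0.1)

    def test_confidence_coverage_of_known_slope(self):
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            y = 0.05 * (YEARS - 1979) + rng.normal(0, 1, 38)
            fit = ols_trend(YEARS, y)
            hits += abs(fit.beta - 0.05) <= 2 * fit.se
        assert hits / n_rep == pytest.approx(0.95, abs=0.03)


class TestTotalChange:
    @pytest.mark.parametrize("beta, expected", [
        (0.050, 1.9), (0.069, 2.6), (0.101, 3.8), (0.0, 0.0)])
    def test_beta_times_span(self, beta, expected):
        assert round(total_change(beta, 38), 1) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            total_change(np.nan)


class TestArComparison:
    def test_white_noise_prefers_no_correction(self):
        rng = np.random.default_rng(7)
        wins = 0
        n_rep = 200
        for _ in range(n_rep):
            y = 0.05 * YEARS + rng.normal(0, 1, 38)
            res = gls_ar_compare(YEARS, y)
            wins += res.aic_ols <= res.aic_ar1
        # asymptotically P(aic_ols <= aic_ar1) = P(chi2_1 <= 2) ~ 0.84
        assert wins / n_rep >= 0.75

    def test_strong_autocorrelation_prefers_ar_structure(self):
        rng = np.random.default_rng(8)
        wins = 0
        n_rep = 120
        for _ in range(n_rep):
            e = np.zeros(38)
            eps = rng.normal(0, 1, 38)
            for t in range(1, 38):
                e[t] = 0.8 * e[t - 1] + eps[t]
            res = gls_ar_compare(YEARS, 0.05 * YEARS + e)
            wins += res.selected != "ols"
        assert wins / n_rep >= 0.8

    def test_minimal_series_returns_three_finite_aics_or_flags(self):
        rng = np.random.default_rng(9)
        res = gls_ar_compare(np.arange(6), rng.normal(0, 1, 6))
        for label, aic in zip(("ols", "ar1", "ar2"), res.as_tuple()):
            assert np.isfinite(aic) or label in res.failures


class TestNormalizedTrend:
    def test_scale_invariance(self):
        rng = np.random.default_rng(10)
        y = 2.0 + 0.03 * (YEARS - 1979) + rng.normal(0, 0.3, 38)
        assert normalized_trend(YEARS, 5.0 * y) == pytest.approx(
            normalized_trend(YEARS, y))

    def test_definition_beta_over_mean(self):
        y = 2.0 + 0.068 * (YEARS - YEARS.mean())
        assert normalized_trend(YEARS, y) == pytest.approx(0.034)

    def test_constant_series_is_zero(self):
        assert normalized_trend(YEARS, np.full(38, 3.0)) == 0.0

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            normalized_trend(YEARS, np.full(38, -1.0))


class TestLogRatioTrend:
    def test_identical_series_flat(self):
        y = np.exp(np.linspace(0, 1, 38))
        res = log_ratio_trend(YEARS, y, y)
        assert res.beta == 0.0
        assert res.t == 0.0

    def test_exact_proportional_divergence(self):
        y_b = np.full(38, 2.0)
        y_a = y_b * np.exp(0.01 * YEARS)
        res = log_ratio_trend(YEARS, y_a, y_b)
        assert res.beta == pytest.approx(0.01)

    def test_nonpositive_years_dropped_with_warning(self):
        y_a = np.full(38, 2.0)
        y_b = np.full(38, 1.0)
        y_a[3] = 0.0
        with pytest.warns(UserWarning):
            res = log_ratio_trend(YEARS, y_a, y_b)
        assert res.n == 37

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            base = np.exp(0.01 * (YEARS - 1979))
            y_a = base * np.exp(rng.normal(0, 0.2, 38))
            y_b = base * np.exp(rng.normal(0, 0.2, 38))
            rejections += log_ratio_trend(YEARS, y_a, y_b).p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.03)


class TestSlopeDifference:
    def test_identical_fits(self):
        rng = np.random.default_rng(12)
        fit = ols_trend(YEARS, 0.1 * YEARS + rng.normal(0, 1, 38))
        res = slope_difference_test(fit, fit)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_three_pooled_se_gap_gives_t_three(self):
        rng = np.random.default_rng(13)
        f1 = ols_trend(YEARS, 0.1 * YEARS + rng.normal(0, 1, 38))
        f2 = ols_trend(YEARS, 0.1 * YEARS + rng.normal(0, 1, 38))
        pooled = np.sqrt(f1.se ** 2 + f2.se ** 2)
        import dataclasses
        f2 = dataclasses.replace(f2, beta=f1.beta - 3 * pooled)
        assert abs(slope_difference_test(f1, f2).t) == pytest.approx(3.0)

    def test_equal_slopes_reject_at_nominal_rate(self):
        rng = np.random.default_rng(14)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            f1 = ols_trend(YEARS, 0.05 * YEARS + rng.normal(0, 1, 38))
            f2 = ols_trend(YEARS, 0.05 * YEARS + rng.normal(0, 1, 38))
            rejections += slope_difference_test(f1, f2).p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.03)


class TestTempResponse:
    def test_exact_linear_response(self):
        rng = np.random.default_rng(15)
        temp = rng.normal(5, 2, 38)
        fit = temp_response(temp, 0.1 * temp)
        assert fit.beta == pytest.approx(0.1)
        assert fit.r == pytest.approx(1.0)

    def test_independent_series_reject_at_nominal_rate(self):
        rng = np.random.default_rng(16)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            fit = temp_response(rng.normal(0, 1, 38), rng.normal(0, 1, 38))
            rejections += fit.p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.03)


class TestPartialRegression:
    @staticmethod
    def _instance(rng, n=38):
        temp = rng.normal(3, 1.5, n)
        rodents = np.abs(rng.normal(3, 2, n))
        fox = np.abs(rng.normal(1, 0.4, n)) + 0.05
        metric = (0.3 + 0.12 * temp + 0.1 * np.sqrt(rodents)
                  - 0.2 * np.log(fox) + rng.normal(0, 0.4, n))
        return metric, temp, rodents, fox

    def test_orthogonal_covariates_leave_slope_unchanged(self):
        rng = np.random.default_rng(17)
        n = 4000  # large n: sample correlations with the covariates vanish
        temp = rng.normal(0, 1, n)
        metric = 0.5 + 0.2 * temp + rng.normal(0, 0.1, n)
        rodents = np.abs(rng.normal(3, 1, n))
        fox = np.abs(rng.normal(1, 0.3, n)) + 0.05
        res = partial_regression(metric, temp, rodents, fox)
        simple = temp_response(temp, metric)
        assert res.beta_p == pytest.approx(simple.beta, abs=0.01)

    def test_residual_on_residual_equals_multiple_regression(self):
        rng = np.random.default_rng(18)
        for _ in range(20):
            metric, temp, rodents, fox = self._instance(rng)
            res = partial_regression(metric, temp, rodents, fox)
            assert res.beta_resid == pytest.approx(res.beta_p, rel=1e-10)

    def test_metric_explained_by_covariates_gives_null_slope(self):
        rng = np.random.default_rng(19)
        n = 2000
        temp = rng.normal(3, 1.5, n)
        rodents = np.abs(rng.normal(3, 2, n))
        fox = np.abs(rng.normal(1, 0.4, n)) + 0.05
        metric = 1.0 + 0.5 * np.sqrt(rodents) - 0.3 * np.log(fox)
        res = partial_regression(metric, temp, rodents, fox)
        assert res.beta_p == pytest.approx(0.0, abs=1e-8)

    def test_zero_fox_handled_by_shifted_log(self):
        rng = np.random.default_rng(20)
        metric, temp, rodents, fox = self._instance(rng)
        fox[0] = 0.0
        res = partial_regression(metric, temp, rodents, fox)
        assert res.fox_log_shift > 0
        assert np.isfinite(res.beta_p)


class TestLaggedResponse:
    def test_exact_lag_one_dependence(self):
        rng = np.random.default_rng(21)
        temp = rng.normal(14, 1, 38)
        metric = np.concatenate([[np.nan], temp[:-1]])  # metric_t = temp_{t-1}
        res = lagged_response(YEARS, metric, YEARS, temp, lags=(1,))
        assert res[0].r2 == pytest.approx(1.0)
        assert res[0].n == 37

    def test_independent_series_r2_near_null_expectation(self):
        rng = np.random.default_rng(22)
        r2s = []
        for _ in range(500):
            res = lagged_response(YEARS, rng.normal(0, 1, 38), YEARS,
                                  rng.normal(0, 1, 38), lags=(1,))
            r2s.append(res[0].r2)
        # E[R^2] = 1/(n-1) for independent Gaussian pairs, n = 37
        assert np.mean(r2s) == pytest.approx(1 / 36, abs=0.01)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            lagged_response([1, 2, 3], [1.0, 2.0, 1.5], [1, 2, 3],
                            [10.0, 11.0, 12.0], lags=(2,))


class TestSignificanceLabels:
    @pytest.mark.parametrize("p, label", [
        (0.01, "significant"), (0.07, "near_significant"),
        (0.5, "ns"), (np.nan, "undefined")])
    def test_band_labels(self, p, label):
        assert significance_label(p) == label
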