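"""Per-pixel trend chain: ARIMA selection, fitted values, median trend,
classification, and the whole-raster map."""

import numpy as np
import pytest

from oceandark._arma import fit_css, fitted_levels
from oceandark.synthetic import TrendScenario, ar1_series, generate_kd_stack
from oceandark.trend import (CLASS_CODES, KdTrendModel, classify_and_predict,
                             fit_pixel, fitted_values, quantile_trend,
                             select_arima, trend_map)


class TestSelectArima:
    def test_linear_series_fitted_exactly(self):
        """A drifted random walk reproduces a deterministic line exactly."""
        y = 0.1 + 0.002 * np.arange(20)
        fit = select_arima(y)
        fv = fitted_values(y, fit)
        assert np.max(np.abs(fv[1:] - y[1:])) <= 1e-6

    def test_constant_series_degenerates(self):
        y = np.full(20, 0.1)
        fit = select_arima(y)
        fv = fitted_values(y, fit)
        assert np.allclose(fv, 0.1)

    def test_short_series_flagged_insufficient(self, years):
        s = np.full(20, np.nan)
        s[:8] = 0.1
        res = fit_pixel(s, years)
        assert res.classification == "insufficient_data"
        assert res.n_valid == 8

    def test_css_aic_selection_agrees_with_statespace_on_strong_ar(self):
        """On a strongly autocorrelated differenced series both engines
        prefer an AR component over white noise."""
        rng = np.random.default_rng(0)
        # build a level series whose differences are AR(1) with phi=0.8
        w = np.empty(40)
        w[0] = 0.0
        for t in range(1, 40):
            w[t] = 0.8 * w[t - 1] + rng.normal(0, 0.01)
        y = 0.5 + np.cumsum(w)
        fit = select_arima(y)
        p, _, q = fit.order
        assert p + q >= 1


class TestFittedValues:
    def test_random_walk_prediction_is_lag_plus_drift(self):
        rng = np.random.default_rng(1)
        y = 0.1 + np.cumsum(rng.normal(0, 0.01, 20))
        fit = fit_css(np.diff(y), 0, 0)
        fv = fitted_levels(y, fit)
        drift = np.diff(y).mean()
        assert np.allclose(fv[1:], y[:-1] + drift, atol=1e-12)

    def test_length_preserved(self):
        y = 0.1 + np.arange(20) * 1e-3
        fv = fitted_values(y, select_arima(y))
        assert len(fv) == len(y)

    def test_first_fitted_equals_first_observation(self):
        rng = np.random.default_rng(2)
        y = 0.1 + rng.normal(0, 0.01, 20)
        fv = fitted_values(y, select_arima(y))
        assert fv[0] == y[0]

    def test_matches_statsmodels_for_random_walk_with_drift(self):
        from statsmodels.tsa.arima.model import ARIMA

        rng = np.random.default_rng(5)
        y = 0.2 + np.cumsum(rng.normal(0.002, 0.01, 20))
        ours = fitted_levels(y, fit_css(np.diff(y), 0, 0))
        sm = ARIMA(y, order=(0, 1, 0), trend="t").fit()
        # identical one-step predictions after the first observation
        assert np.allclose(ours[1:], sm.fittedvalues[1:], atol=1e-4)


class TestQuantileTrend:
    def test_collinear_points_recover_line(self, years):
        fitted = 0.1 + 0.002 * (years - 2003)
        slope, intercept, (lo, hi) = quantile_trend(fitted, years)
        assert slope == pytest.approx(0.002, abs=1e-9)
        assert intercept + slope * 2003 == pytest.approx(0.1, abs=1e-6)
        assert lo > 0

    def test_constant_fitted_gives_zero_slope(self, years):
        slope, _, (lo, hi) = quantile_trend(np.full(20, 0.1), years)
        assert slope == 0.0
        assert lo <= 0.0 <= hi

    def test_sign_flip_equivariance(self, years):
        rng = np.random.default_rng(8)
        fitted = 0.1 + 0.001 * np.arange(20) + rng.normal(0, 0.005, 20)
        s1, _, (lo1, hi1) = quantile_trend(fitted, years)
        s2, _, (lo2, hi2) = quantile_trend(-fitted, years)
        assert s2 == pytest.approx(-s1, abs=1e-9)
        assert lo2 == pytest.approx(-hi1, abs=1e-6)
        assert hi2 == pytest.approx(-lo1, abs=1e-6)

    def test_rank_ci_calibrated_on_iid_noise(self, years):
        """The iid-variant rank CI holds near-nominal level on iid series."""
        rng = np.random.default_rng(11)
        rejections = 0
        n = 400
        for _ in range(n):
            y = 0.1 + rng.normal(0, 0.005, 20)
            _, _, (lo, hi) = quantile_trend(y, years)
            rejections += (lo > 0) or (hi < 0)
        assert rejections / n <= 0.10


class TestClassifyAndPredict:
    def test_increasing_case_endpoint_difference(self, years):
        res = classify_and_predict(0.002, 0.1 - 0.002 * 2003, (0.001, 0.003),
                                   np.full(20, 0.1), years)
        assert res.classification == "increasing"
        assert res.kd_end - res.kd_start == pytest.approx(0.038, abs=1e-9)

    def test_no_change_falls_back_to_median(self, years):
        raw = np.full(20, 0.1)
        res = classify_and_predict(0.0005, 0.0, (-0.001, 0.001), raw, years)
        assert res.classification == "no_change"
        assert res.kd_start == res.kd_end == pytest.approx(0.1)

    def test_decreasing_symmetric(self, years):
        res = classify_and_predict(-0.002, 0.1 + 0.002 * 2003, (-0.003, -0.001),
                                   np.full(20, 0.1), years)
        assert res.classification == "decreasing"
        assert res.kd_start - res.kd_end == pytest.approx(0.038, abs=1e-9)


class TestTrendMap:
    def test_planted_block_recovered(self, linear_stack):
        stack, truth = linear_stack
        results = KdTrendModel(stack).fit()
        block = truth.classification == 1
        recovered = results.class_mask("increasing")[block].mean()
        assert recovered >= 0.95
        # zero-noise null pixels never classified as changing
        null = truth.classification == 0
        assert results.class_mask("no_change")[null].all()

    def test_slope_recovery_zero_noise(self, linear_stack):
        stack, truth = linear_stack
        results = KdTrendModel(stack).fit()
        assert np.nanmax(np.abs(results.slope - truth.slope)) <= 1e-3

    def test_worker_count_does_not_change_results(self, linear_stack):
        stack, _ = linear_stack
        r1 = KdTrendModel(stack).fit(workers=1)
        r2 = KdTrendModel(stack).fit(workers=2)
        assert np.array_equal(r1.slope, r2.slope, equal_nan=True)
        assert np.array_equal(r1.classification, r2.classification)

    def test_all_missing_pixel_is_insufficient(self, small_grid, years):
        sc = TrendScenario(missing_fraction=0.0, noise_sigma=0.002, seed=4)
        stack, _ = generate_kd_stack(small_grid, sc)
        stack.values[:, 0, 0] = np.nan
        stack.missing[:, 0, 0] = True
        results = trend_map(stack)
        assert results.classification[0, 0] == CLASS_CODES["insufficient_data"]

    def test_summary_mentions_counts(self, linear_stack):
        stack, _ = linear_stack
        text = KdTrendModel(stack).fit().summary()
        assert "increasing" in text and "16 x 16" in text


class TestPowerAndSign:
    def test_strong_trend_detected_with_correct_sign(self, years):
        """A slope worth 3 noise SDs over the span is reliably recovered."""
        rng = np.random.default_rng(21)
        sigma, span = 0.005, 19
        slope = 3 * sigma / span
        hits = 0
        n = 150
        for _ in range(n):
            s = ar1_series(20, 0.1, slope, 0.5, sigma, rng)
            hits += fit_pixel(s, years).classification == "increasing"
        assert hits / n >= 0.8
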