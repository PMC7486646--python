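import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from bloodcast import (DifferenceSpec, GeneratorConfig, acf, difference,
                       fit_ma, forecast_arima, generate_series,
                       invert_difference, ljung_box, mape, pacf, select_order)
from bloodcast.arima import _css_residuals


def simulate_ma(theta, n, seed):
    """w_t = eps_t - sum theta_j eps_{t-j} (the package's sign convention)."""
    rng = np.random.default_rng(seed)
    eps = rng.normal(size=n + len(theta))
    w = eps[len(theta):].copy()
    for j, th in enumerate(theta, start=1):
        w -= th * eps[len(theta) - j:len(theta) - j + n]
    return w


class TestDifferencing:
    def test_hand_arithmetic(self):
        out = difference([1, 3, 6, 10], DifferenceSpec(d=1, D=0))
        assert np.array_equal(out, [2, 3, 4])

    def test_constant_series_to_zeros(self):
        assert np.allclose(difference(np.full(20, 5.0),
                                      DifferenceSpec(d=1, D=0)), 0.0)

    def test_trend_plus_weekly_seasonal_annihilated(self):
        t = np.arange(70)
        seasonal = np.array([9, 1, 4, 7, 2, 8, 5])[t % 7]
        y = 5 + 2 * t + seasonal
        out = difference(y, DifferenceSpec(d=1, D=1, s=7))
        assert np.allclose(out, 0.0)

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="too short"):
            difference(np.arange(8), DifferenceSpec(d=1, D=1, s=7))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(y=hnp.arrays(float, st.integers(20, 60),
                        elements=st.floats(-1e3, 1e3)),
           d=st.integers(0, 2), D=st.integers(0, 1))
    def test_roundtrip_identity(self, y, d, D):
        spec = DifferenceSpec(d=d, D=D, s=7)
        w = difference(y, spec)
        back = invert_difference(w, y[:spec.burn_in], spec)
        assert np.allclose(back, y[spec.burn_in:], atol=1e-8)

    def test_zero_future_diffs_continue_last_week_plus_increment(self):
        """With (d=1, D=1, s=7), zero future differences extend the series
        by last week's values plus the last weekly increment (closed-form
        recursion checked by hand on a length-16 series)."""
        y = np.array([3., 1., 4., 1., 5., 9., 2., 6., 5., 3., 5., 8., 9., 7.,
                      9., 3.])
        spec = DifferenceSpec(d=1, D=1, s=7)
        fc = invert_difference(np.zeros(7), y[-spec.burn_in:], spec)
        # hand recursion: y_t = y_{t-1} + y_{t-7} - y_{t-8}
        expect = []
        ext = list(y)
        for _ in range(7):
            ext.append(ext[-1] + ext[-7] - ext[-8])
            expect.append(ext[-1])
        assert np.allclose(fc, expect)

    def test_no_differencing_is_identity(self):
        w = np.arange(5.0)
        assert np.array_equal(
            invert_difference(w, np.array([]), DifferenceSpec(0, 0)), w)


class TestCorrelograms:
    def test_white_noise_acf_within_bounds(self):
        n, hits, total = 5000, 0, 0
        for seed in range(40):
            x = np.random.default_rng(seed).normal(size=n)
            r = acf(x, 10)
            hits += int(np.sum(np.abs(r) < 3 / np.sqrt(n)))
            total += 10
        assert hits / total >= 0.95

    def test_ar1_acf_matches_theory(self):
        rng = np.random.default_rng(11)
        n, phi = 5000, 0.8
        x = np.zeros(n)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + rng.normal()
        assert acf(x, 1)[0] == pytest.approx(phi, abs=0.05)

    def test_periodic_series_peaks_at_period(self):
        x = np.tile([9, 1, 4, 7, 2, 8, 5], 40).astype(float)
        r = acf(x, 7)
        assert r[6] > max(r[:6])

    def test_constant_series_reported_absent(self):
        assert np.all(np.isnan(acf(np.full(30, 2.0), 5)))
        assert np.all(np.isnan(pacf(np.full(30, 2.0), 5)))

    def test_against_statsmodels(self):
        import statsmodels.api as sm
        x = np.random.default_rng(12).normal(size=400).cumsum()
        assert np.allclose(acf(x, 10), sm.tsa.acf(x, nlags=10, fft=False)[1:],
                           atol=1e-10)
        assert np.allclose(pacf(x, 10), sm.tsa.pacf(x, nlags=10,
                                                    method="ldb")[1:],
                           atol=1e-8)


class TestFitMA:
    def test_white_noise_coefficients_near_zero(self):
        w = np.random.default_rng(13).normal(size=2000)
        fit = fit_ma(w, 2)
        assert np.all(np.abs(fit.theta) < 0.07)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ma1_recovery(self, seed):
        w = simulate_ma([0.6], 2000, seed)
        fit = fit_ma(w, 1)
        assert 0.55 <= fit.theta[0] <= 0.65

    def test_optimum_matches_brute_force_grid(self):
        """The optimiser's SSE minimum agrees with an exhaustive 1-D grid
        over theta within 0.1%."""
        w = simulate_ma([0.6], 2000, 4)
        fit = fit_ma(w, 1)
        grid = np.arange(-0.99, 0.995, 0.005)
        sses = [float(np.sum(_css_residuals(np.array([-th]), w) ** 2))
                for th in grid]
        assert fit.sigma2 * fit.n_obs <= min(sses) * 1.001

    def test_invertibility_enforced(self):
        # theta = 1.5 is non-invertible; the fit must land inside the circle
        w = simulate_ma([1.5], 500, 5)
        fit = fit_ma(w, 1)
        roots = np.roots(fit.ma_poly()[::-1])
        assert np.all(np.abs(roots) >= 1.0 - 1e-6)

    def test_matches_statsmodels_css(self):
        import statsmodels.api as sm
        w = simulate_ma([0.5, -0.3], 1500, 6)
        fit = fit_ma(w, 2)
        ref = sm.tsa.ARIMA(w, order=(0, 0, 2), trend="n").fit(method="innovations_mle")
        # statsmodels convention is 1 + b1 B + b2 B^2 -> b = -theta
        assert np.allclose(fit.theta, -ref.params[:2], atol=0.03)

    def test_t_statistics_significant_for_real_coefficient(self):
        fit = fit_ma(simulate_ma([0.6], 2000, 7), 1)
        assert abs(fit.t_values[0]) > 10

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="3q"):
            fit_ma(np.arange(9.0), 3)


class TestSelectOrder:
    def test_bic_selects_ma1_majority(self):
        hits = sum(select_order(simulate_ma([0.6], 500, seed),
                                range(1, 8)) == 1
                   for seed in range(50))
        assert hits / 50 >= 0.80

    def test_single_candidate_returned(self):
        assert select_order(simulate_ma([0.6], 300, 0), [3]) == 3

    def test_lag7_process_prefers_q7_over_q1(self):
        w = simulate_ma([0, 0, 0, 0, 0, 0, 0.7], 1500, 8)
        assert select_order(w, [1, 7]) == 7

    def test_useless_parameter_raises_bic(self):
        w = np.random.default_rng(9).normal(size=1000)
        assert fit_ma(w, 2).bic > fit_ma(w, 1).bic


class TestLjungBox:
    def test_df_structure_with_seven_parameters(self):
        res = ljung_box(np.random.default_rng(0).normal(size=400),
                        [6, 12, 18, 24, 30], n_fitted_params=7)
        assert [r.df for r in res] == [0, 5, 11, 17, 23]
        assert res[0].p_value is None
        assert all(r.p_value is not None for r in res[1:])

    def test_size_under_null(self):
        passes = 0
        reps = 200
        for seed in range(reps):
            eps = np.random.default_rng(seed).normal(size=1000)
            (res,) = ljung_box(eps, [12])
            passes += res.p_value > 0.05
        assert 0.90 <= passes / reps <= 0.99

    def test_power_against_ar1_residuals(self):
        rng = np.random.default_rng(10)
        x = np.zeros(1000)
        for t in range(1, 1000):
            x[t] = 0.7 * x[t - 1] + rng.normal()
        (res,) = ljung_box(x, [12])
        assert res.p_value < 0.01

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        eps = np.random.default_rng(14).normal(size=300)
        ours = ljung_box(eps, [5, 10])
        ref = sm.stats.acorr_ljungbox(eps, lags=[5, 10])
        assert np.allclose([r.q_stat for r in ours], ref["lb_stat"],
                           atol=1e-8)
        assert np.allclose([r.p_value for r in ours], ref["lb_pvalue"],
                           atol=1e-10)

    def test_all_zero_df_warns(self):
        with pytest.warns(UserWarning, match="zero degrees"):
            ljung_box(np.random.default_rng(1).normal(size=100), [3, 5],
                      n_fitted_params=7)


class TestForecast:
    def test_zero_theta_forecasts_continue_deterministic_structure(
            self, deterministic_config):
        series = generate_series(deterministic_config)
        spec = DifferenceSpec(1, 1, 7)
        fit = fit_ma(difference(series.counts, spec), 7)
        zero_fit = fit.__class__(q=7, theta=np.zeros(7), sigma2=fit.sigma2,
                                 residuals=fit.residuals, loglik=0.0,
                                 bic=0.0, n_obs=fit.n_obs)
        fc = forecast_arima(series, spec, zero_fit, horizon=7)
        expect = invert_difference(np.zeros(7), series.counts[-8:], spec)
        assert np.allclose(fc, expect)

    def test_horizon_capped_at_seven(self, default_series):
        spec = DifferenceSpec(1, 1, 7)
        fit = fit_ma(difference(default_series.counts, spec), 1)
        with pytest.raises(ValueError, match="horizon"):
            forecast_arima(default_series, spec, fit, horizon=8)

    def test_end_to_end_small_noise_mape_below_two_percent(self):
        cfg = GeneratorConfig(n_weeks=61, annual_amplitude=0.02,
                              trend_slope=0.9, noise_sd=10.0,
                              holiday_rate=0.0, seed=21)
        series = generate_series(cfg)
        train = type(series)(series.dates[:-7], series.counts[:-7])
        spec = DifferenceSpec(1, 1, 7)
        fit = fit_ma(difference(train.counts, spec), 7)
        fc = forecast_arima(train, spec, fit, horizon=7)
        assert mape(series.counts[-7:], fc) < 2.0
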