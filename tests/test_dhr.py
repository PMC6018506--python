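"""State-space construction, Kalman filtering/smoothing, NVR optimization,
DHR fitting, forecasting and trend-slope extraction."""

import numpy as np
import pytest

from condemnwatch.dhr import (dhr_model_spectrum, fit_dhr, forecast,
                              forecast_from_filter, optimize_nvr, trend_slope)
from condemnwatch.periodicity import ARSpectrum, default_grid
from condemnwatch.statespace import (DHRModelSpec, build_state_space,
                                     kalman_filter, kalman_smooth,
                                     observation_matrix)
from condemnwatch.synthetic import (HarmonicSpec, ReasonScenario,
                                    simulate_dhr_series)

from conftest import gls_state_oracle


class TestStateSpaceConstruction:
    def test_no_harmonics_gives_two_state_local_linear_trend(self):
        spec = DHRModelSpec(frequencies=(), nvr_trend=0.1, nvr_harmonics=(),
                            sigma2=1.0)
        F, Q, sigma2 = build_state_space(spec)
        np.testing.assert_array_equal(F, [[1, 1], [0, 1]])
        np.testing.assert_array_equal(np.diag(Q), [0.0, 0.1])

    def test_two_harmonics_give_six_states_and_observation_row(self):
        spec = DHRModelSpec(frequencies=(1 / 12, 1 / 6), nvr_trend=0.0,
                            nvr_harmonics=(0.01, 0.01), sigma2=2.0)
        F, Q, _ = build_state_space(spec)
        assert F.shape == (6, 6)
        Z = observation_matrix(spec, np.array([0]))
        assert Z.shape == (1, 6)
        np.testing.assert_allclose(Z[0], [1, 0, 1, 0, 1, 0])

    def test_zero_nvrs_give_zero_process_noise(self):
        spec = DHRModelSpec(frequencies=(1 / 12,), nvr_trend=0.0,
                            nvr_harmonics=(0.0,), sigma2=1.0)
        _, Q, _ = build_state_space(spec)
        assert np.all(Q == 0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            DHRModelSpec(frequencies=(0.7,), nvr_trend=0.0, nvr_harmonics=(0.1,),
                         sigma2=1.0)
        with pytest.raises(ValueError):
            DHRModelSpec(frequencies=(1 / 12,), nvr_trend=-1.0,
                         nvr_harmonics=(0.1,), sigma2=1.0)
        with pytest.raises(ValueError):
            DHRModelSpec(frequencies=(1 / 12,), nvr_trend=0.0,
                         nvr_harmonics=(0.1,), sigma2=0.0)


class TestKalmanFilterSmoother:
    def test_local_level_converges_to_constant(self):
        """RW level with zero process noise on a constant series -> level c."""
        spec = DHRModelSpec(frequencies=(), nvr_trend=0.0, nvr_harmonics=(),
                            sigma2=1.0, trend="rw")
        y = np.full(60, 3.7) + 1e-9  # exactly constant up to prior scaling
        filt = kalman_filter(y, spec, P0=np.array([[1e7]]))
        assert filt.x_filt[-1, 0] == pytest.approx(3.7, abs=1e-5)
        assert abs(filt.innovations[-1]) < 1e-5

    @pytest.mark.parametrize("seed,freqs,n", [
        (0, (), 8), (1, (0.25,), 10), (2, (1 / 12,), 12), (3, (0.1, 0.3), 12)])
    def test_filter_and_smoother_match_gls_oracle(self, seed, freqs, n):
        """Posterior state means equal the dense stacked-GLS solution."""
        rng = np.random.default_rng(seed)
        spec = DHRModelSpec(frequencies=freqs, nvr_trend=0.02,
                            nvr_harmonics=(0.05,) * len(freqs), sigma2=0.5)
        y = rng.normal(0, 1, n)
        P0 = 1e7 * np.var(y) * np.eye(spec.dim)
        filt = kalman_filter(y, spec, P0=P0)
        smooth = kalman_smooth(filt)
        np.testing.assert_allclose(smooth.x_smooth, gls_state_oracle(y, spec, P0),
                                   atol=1e-8)
        for t in range(n):
            np.testing.assert_allclose(
                filt.x_filt[t], gls_state_oracle(y[: t + 1], spec, P0)[t], atol=1e-8)

    def test_missing_observations_are_skipped_not_fatal(self):
        spec = DHRModelSpec(frequencies=(), nvr_trend=0.01, nvr_harmonics=(),
                            sigma2=1.0)
        y = np.random.default_rng(4).normal(size=30)
        y[10:13] = np.nan
        filt = kalman_filter(y, spec)
        assert np.isnan(filt.innovations[10:13]).all()
        assert np.isfinite(filt.loglik)

    def test_infinite_input_is_hard_error(self):
        spec = DHRModelSpec(frequencies=(), nvr_trend=0.0, nvr_harmonics=(),
                            sigma2=1.0)
        with pytest.raises(ValueError, match="non-finite"):
            kalman_filter(np.array([1.0, np.inf, 2.0]), spec)

    def test_smoother_equals_filter_at_last_point(self):
        spec = DHRModelSpec(frequencies=(1 / 12,), nvr_trend=0.01,
                            nvr_harmonics=(0.02,), sigma2=1.0)
        y = np.random.default_rng(5).normal(size=48)
        filt = kalman_filter(y, spec)
        smooth = kalman_smooth(filt)
        np.testing.assert_allclose(smooth.x_smooth[-1], filt.x_filt[-1], rtol=1e-12)

    def test_smoothed_variance_never_exceeds_filtered(self):
        spec = DHRModelSpec(frequencies=(1 / 6,), nvr_trend=0.01,
                            nvr_harmonics=(0.02,), sigma2=1.0)
        y = np.random.default_rng(6).normal(size=48)
        filt = kalman_filter(y, spec)
        smooth = kalman_smooth(filt)
        diag_f = np.diagonal(filt.P_filt, axis1=1, axis2=2)
        diag_s = np.diagonal(smooth.P_smooth, axis1=1, axis2=2)
        assert np.all(diag_s <= diag_f + 1e-9)

    def test_zero_nvr_smoother_reproduces_noiseless_line(self):
        spec = DHRModelSpec(frequencies=(), nvr_trend=0.0, nvr_harmonics=(),
                            sigma2=1.0)
        t = np.arange(40)
        y = 1.5 + 0.25 * t
        filt = kalman_filter(y, spec, diffuse_scale=1e8,
                             x0=np.array([y[0], 0.0]))
        smooth = kalman_smooth(filt)
        np.testing.assert_allclose(smooth.x_smooth[:, 0], y, atol=1e-8)
        np.testing.assert_allclose(smooth.x_smooth[:, 1], 0.25, atol=1e-8)

    def test_agrees_with_statsmodels_local_level(self):
        """Independent route: statsmodels' Kalman filter on the same model."""
        import statsmodels.api as sm

        y = np.random.default_rng(7).normal(loc=2.0, size=80)
        spec = DHRModelSpec(frequencies=(), nvr_trend=0.3, nvr_harmonics=(),
                            sigma2=1.5, trend="rw")
        mod = sm.tsa.UnobservedComponents(y, level="llevel")
        with mod.fix_params({"sigma2.irregular": 1.5, "sigma2.level": 0.45}):
            res = mod.fit(disp=False)
        filt = kalman_filter(y, spec, diffuse_scale=1e9 / np.var(y))
        # statsmodels uses exact diffuse initialisation; compare after burn-in
        np.testing.assert_allclose(filt.x_filt[5:, 0],
                                   res.filtered_state[0][5:], atol=1e-6)

    def test_innovations_white_for_correctly_specified_model(self):
        """Ljung-Box on standardized innovations passes at the 1% level in
        >= 90% of seeded replicates."""
        from statsmodels.stats.diagnostic import acorr_ljungbox

        scenario = ReasonScenario(
            name="lb", baseline_rate=1e-3, trend_slope=0.0,
            harmonics=(HarmonicSpec(12.0, 3e-4, 0.5),),
            nvr_trend=1e-5, nvr_harmonic=3e-3, sigma=5e-5)
        spec = DHRModelSpec(frequencies=(1 / 12,), nvr_trend=1e-5,
                            nvr_harmonics=(3e-3,), sigma2=(5e-5) ** 2)
        passed = 0
        n_rep = 20
        for seed in range(n_rep):
            y, _ = simulate_dhr_series(scenario, seed=seed)
            filt = kalman_filter(y.to_numpy(), spec)
            std = (filt.innovations[filt.n_burn:]
                   / np.sqrt(filt.innovation_variances[filt.n_burn:]))
            p = acorr_ljungbox(std, lags=[12])["lb_pvalue"].iloc[0]
            passed += p > 0.01
        assert passed >= 0.9 * n_rep


class TestModelSpectrum:
    GRID = default_grid(256)

    def test_zero_nvrs_give_flat_white_noise_floor(self):
        spec = DHRModelSpec(frequencies=(1 / 12,), nvr_trend=0.0,
                            nvr_harmonics=(0.0,), sigma2=2.5)
        grid = self.GRID[np.abs(self.GRID - 1 / 12) > 1e-3]
        np.testing.assert_allclose(dhr_model_spectrum(spec, grid), 2.5)

    def test_single_harmonic_peaks_next_to_its_frequency(self):
        spec = DHRModelSpec(frequencies=(0.25,), nvr_trend=0.0,
                            nvr_harmonics=(0.05,), sigma2=1.0)
        grid = self.GRID[np.abs(self.GRID - 0.25) > 1e-4]
        power = dhr_model_spectrum(spec, grid)
        assert abs(grid[np.argmax(power)] - 0.25) < 0.01

    def test_contribution_linear_in_nvr(self):
        grid = self.GRID[np.abs(self.GRID - 0.25) > 1e-3]
        base = DHRModelSpec(frequencies=(0.25,), nvr_trend=0.0,
                            nvr_harmonics=(0.0,), sigma2=1.0)
        one = DHRModelSpec(frequencies=(0.25,), nvr_trend=0.0,
                           nvr_harmonics=(0.02,), sigma2=1.0)
        two = DHRModelSpec(frequencies=(0.25,), nvr_trend=0.0,
                           nvr_harmonics=(0.04,), sigma2=1.0)
        s0 = dhr_model_spectrum(base, grid)
        s1 = dhr_model_spectrum(one, grid)
        s2 = dhr_model_spectrum(two, grid)
        np.testing.assert_allclose(s2 - s0, 2 * (s1 - s0), rtol=1e-10)

    def test_singular_grid_point_is_hard_error(self):
        spec = DHRModelSpec(frequencies=(0.25,), nvr_trend=0.01,
                            nvr_harmonics=(0.01,), sigma2=1.0)
        with pytest.raises(ValueError, match="singularity"):
            dhr_model_spectrum(spec, np.array([0.1, 0.25]))


class TestNVROptimization:
    def test_round_trip_recovery_from_own_spectrum(self):
        """NVRs recovered within +/-0.5 log10 when the target is the model's
        own pseudo-spectrum."""
        grid = default_grid()
        truth = DHRModelSpec(frequencies=(1 / 12, 1 / 6), nvr_trend=1e-4,
                             nvr_harmonics=(3e-3, 1e-3), sigma2=1.0)
        step = grid[1] - grid[0]
        mask = np.ones(len(grid), bool)
        for f in truth.frequencies:
            mask &= np.abs(grid - f) > 0.75 * step
        ar_spec = ARSpectrum(order=0, ar_coefficients=np.array([]),
                             innovation_variance=1.0, frequency_grid=grid[mask],
                             power=dhr_model_spectrum(truth, grid[mask]))
        opt = optimize_nvr(ar_spec, truth.frequencies)
        assert np.log10(opt.nvr_trend) == pytest.approx(-4, abs=0.5)
        assert np.log10(opt.nvr_harmonics[0]) == pytest.approx(np.log10(3e-3), abs=0.5)
        assert np.log10(opt.nvr_harmonics[1]) == pytest.approx(-3, abs=0.5)
        assert opt.sigma2 == pytest.approx(1.0, rel=0.1)

    def test_flat_spectrum_drives_harmonic_nvrs_to_zero(self):
        grid = default_grid()
        ar_spec = ARSpectrum(order=0, ar_coefficients=np.array([]),
                             innovation_variance=1.0, frequency_grid=grid,
                             power=np.full(len(grid), 2.5))
        opt = optimize_nvr(ar_spec, (1 / 12, 1 / 6))
        assert all(v < 1e-6 for v in opt.nvr_harmonics)
        assert opt.sigma2 == pytest.approx(2.5, rel=0.05)


class TestFitDHR:
    def test_noiseless_trend_plus_sinusoid_is_perfectly_fitted(self):
        t = np.arange(120)
        y = 2.0 + 0.01 * t + 0.5 * np.sin(2 * np.pi * t / 12 + 0.3)
        fit = fit_dhr(y, periods=[12.0])
        assert fit.r_squared > 0.999

    def test_decomposition_identity_exact(self):
        scenario = ReasonScenario(
            name="d", baseline_rate=1e-3,
            harmonics=(HarmonicSpec(12.0, 3e-4, 0.1),),
            nvr_trend=1e-5, nvr_harmonic=3e-3, sigma=5e-5)
        y, _ = simulate_dhr_series(scenario, seed=11)
        fit = fit_dhr(y.to_numpy())
        recon = fit.trend + fit.seasonal + fit.residuals
        np.testing.assert_allclose(recon, y.to_numpy(), rtol=0, atol=1e-15)

    def test_white_noise_with_forced_harmonic_scores_near_zero(self):
        y = np.random.default_rng(12).normal(size=120)
        fit = fit_dhr(y, periods=[12.0])
        assert fit.r_squared < 0.3

    def test_seasonal_component_recovered_from_simulation(self):
        scenario = ReasonScenario(
            name="r", baseline_rate=8.5e-4, trend_slope=-1e-6,
            harmonics=(HarmonicSpec(12.0, 3.5e-4, 0.4), HarmonicSpec(6.0, 1.2e-4, 1.1)),
            nvr_trend=1e-5, nvr_harmonic=5e-3, sigma=4e-5)
        y, truth = simulate_dhr_series(scenario, seed=13)
        fit = fit_dhr(y.to_numpy())
        assert np.corrcoef(fit.seasonal, truth.Q)[0, 1] > 0.9


class TestForecast:
    def test_deterministic_fit_extends_the_closed_form(self):
        t = np.arange(120)
        y = 2.0 + 0.01 * t + 0.5 * np.sin(2 * np.pi * t / 12 + 0.3)
        fit = fit_dhr(y, periods=[12.0], nvr_trend=0.0, nvr_harmonics=0.0,
                      sigma2=1e-12, diffuse_scale=1e9)
        fc = forecast(fit, 12)
        t_future = np.arange(120, 132)
        expected = 2.0 + 0.01 * t_future + 0.5 * np.sin(2 * np.pi * t_future / 12 + 0.3)
        np.testing.assert_allclose(fc.point, expected, atol=1e-6)

    def test_se_nondecreasing_in_horizon(self):
        scenario = ReasonScenario(
            name="s", baseline_rate=1e-3,
            harmonics=(HarmonicSpec(12.0, 3e-4, 0.0),),
            nvr_trend=1e-5, nvr_harmonic=3e-3, sigma=5e-5)
        y, _ = simulate_dhr_series(scenario, seed=14)
        fit = fit_dhr(y.to_numpy())
        fc = forecast(fit, 12)
        assert np.all(np.diff(fc.se) >= -1e-15)
        np.testing.assert_allclose(fc.upper - fc.point, fc.point - fc.lower,
                                   rtol=1e-12)

    def test_forecast_equals_filter_prediction_with_updates_withheld(self):
        """The h-step forecast from origin t matches filtering the series with
        the post-origin observations masked out."""
        scenario = ReasonScenario(
            name="c", baseline_rate=1e-3,
            harmonics=(HarmonicSpec(12.0, 3e-4, 0.7),),
            nvr_trend=1e-5, nvr_harmonic=3e-3, sigma=5e-5)
        y, _ = simulate_dhr_series(scenario, seed=15)
        yv = y.to_numpy()
        spec = DHRModelSpec(frequencies=(1 / 12,), nvr_trend=1e-5,
                            nvr_harmonics=(3e-3,), sigma2=(5e-5) ** 2)
        origin, h = 99, 6
        filt = kalman_filter(yv[: origin + 1], spec)
        fc = forecast_from_filter(filt, origin, h)
        masked = yv.copy()
        masked[origin + 1:] = np.nan
        filt_masked = kalman_filter(masked, spec)
        Z = filt_masked.Z
        pred = np.array([Z[origin + k] @ filt_masked.x_pred[origin + k]
                         for k in range(1, h + 1)])
        np.testing.assert_allclose(fc.point, pred, rtol=1e-10)


class TestTrendSlope:
    def test_constant_series_is_stable(self):
        report = trend_slope(np.full(24, 0.4))
        assert report.slope == pytest.approx(0.0, abs=1e-10)
        assert report.classification == "stable"

    def test_noiseless_line_recovers_slope(self):
        y = 2.0 + 0.3 * np.arange(36)
        report = trend_slope(y)
        assert report.slope == pytest.approx(0.3, abs=1e-8)
        assert report.classification == "increasing"

    def test_matches_normal_equations_ols_on_noisy_line(self):
        rng = np.random.default_rng(16)
        t = np.arange(84, dtype=float)
        y = 1.0 - 0.02 * t + rng.normal(0, 0.5, 84)
        X = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.solve(X.T @ X, X.T @ y)  # brute-force normal equations
        report = trend_slope(y)
        assert report.slope == pytest.approx(beta[1], abs=1e-8)
        assert report.classification == "decreasing"

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            trend_slope(np.array([1.0, 2.0]))
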