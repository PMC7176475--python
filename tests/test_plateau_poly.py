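import numpy as np
import pytest

from navakit import (
    AlgorithmConfig,
    BreathSeries,
    DomainError,
    ValidationError,
    build_plateau_model,
    fit_rwls_poly,
    flow_inspirations,
    info_function,
    tidal_volumes,
)


def half_sine_flow(fs=62.5, amp=0.5, dur=1.0, pad=2.0):
    n_pad, n = int(pad * fs), int(dur * fs)
    flow = np.zeros(2 * n_pad + n)
    flow[n_pad: n_pad + n] = amp * np.sin(np.pi * (np.arange(n) + 0.5) / n)
    return flow


class TestFlowInspirations:
    def test_half_sine_lobe_found(self):
        ivs = flow_inspirations(half_sine_flow(), 62.5)
        assert len(ivs) == 1
        assert ivs[0].length == pytest.approx(62.5, abs=2)

    def test_strictly_negative_flow_empty(self):
        assert flow_inspirations(-np.ones(500), 62.5) == []

    def test_sub_min_duration_blip_discarded(self):
        flow = np.zeros(500)
        flow[100:103] = 0.3  # 48 ms at 62.5 Hz < 0.16 s
        assert flow_inspirations(flow, 62.5, min_dur=0.16) == []


class TestTidalVolumes:
    def test_rectangular_pulse_exact(self):
        fs = 62.5
        flow = np.zeros(500)
        n = int(fs)  # exactly 1 s of 0.5 L/s
        flow[100: 100 + n] = 0.5
        ivs = flow_inspirations(flow, fs)
        vt = tidal_volumes(flow, ivs, fs)
        assert vt.y[0] == pytest.approx(0.5 * n / fs)

    def test_half_sine_matches_analytic(self):
        fs, amp, dur = 62.5, 0.5, 1.0
        flow = half_sine_flow(fs, amp, dur)
        vt = tidal_volumes(flow, flow_inspirations(flow, fs), fs)
        assert vt.y[0] == pytest.approx(2 * amp * dur / np.pi, rel=0.01)

    @pytest.mark.parametrize("fs", [62.5, 125.0, 250.0])
    def test_discretization_error_shrinks_with_fs(self, fs):
        amp, dur = 0.5, 1.0
        flow = half_sine_flow(fs, amp, dur)
        vt = tidal_volumes(flow, flow_inspirations(flow, fs), fs)
        analytic = 2 * amp * dur / np.pi
        assert abs(vt.y[0] - analytic) / analytic < 1.0 / fs

    def test_linearity_in_flow(self):
        fs = 62.5
        flow = half_sine_flow(fs)
        ivs = flow_inspirations(flow, fs)
        v1 = tidal_volumes(flow, ivs, fs).y
        v3 = tidal_volumes(3 * flow, ivs, fs).y
        np.testing.assert_allclose(v3, 3 * v1, rtol=1e-12)

    def test_empty_interval_list(self):
        assert len(tidal_volumes(np.zeros(10), [], 62.5)) == 0


def reference_irls(x, y, order, c=4.685, iters=50):
    """Plain restatement of the reweighting scheme, kept independent of the
    implementation under test."""
    t = (x - x.min()) / (x.max() - x.min())
    V = np.vander(t, order + 1, increasing=True)
    beta = np.linalg.lstsq(V, y, rcond=None)[0]
    w = np.ones_like(y)
    for _ in range(iters):
        r = y - V @ beta
        scale = np.median(np.abs(r - np.median(r))) / 0.6745
        if scale <= 0:
            break
        u = r / (c * scale)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        sw = np.sqrt(w)
        beta = np.linalg.lstsq(V * sw[:, None], y * sw, rcond=None)[0]
    return beta, w


class TestRwlsPoly:
    def test_noiseless_cubic_matches_ols(self, cfg):
        x = np.linspace(0, 1000, 60)
        y = 1 + 0.5 * x - 0.002 * x**2 + 1e-6 * x**3
        coeffs, w, (lo, hi) = fit_rwls_poly(x, y, 10, cfg)
        t = (x - lo) / (hi - lo)
        fitted = np.polynomial.polynomial.polyval(t, coeffs)
        np.testing.assert_allclose(fitted, y, rtol=1e-6)
        np.testing.assert_allclose(w, 1.0)

    def test_gross_outliers_downweighted(self, cfg):
        rng = np.random.default_rng(8)
        x = np.linspace(0, 1000, 100)
        y = 5 + 0.01 * x + rng.normal(0, 0.1, x.size)
        out_idx = rng.choice(x.size, 5, replace=False)
        y[out_idx] += 10 * np.ptp(y)
        _, w, _ = fit_rwls_poly(x, y, 10, cfg)
        assert np.all(w[out_idx] < 0.1)
        # independent restatement of the scheme agrees on the rejections
        _, w_ref = reference_irls(x, y, 10)
        assert np.all(w_ref[out_idx] < 0.1)

    def test_agrees_with_statsmodels_on_outliers(self, cfg):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(9)
        x = np.linspace(0, 100, 80)
        y = 2 + 0.05 * x + rng.normal(0, 0.2, x.size)
        out_idx = [10, 40, 70]
        y[out_idx] += 30
        coeffs, w, (lo, hi) = fit_rwls_poly(x, y, 3, cfg)
        t = (x - lo) / (hi - lo)
        V = np.vander(t, 4, increasing=True)
        rlm = sm.RLM(y, V, M=sm.robust.norms.TukeyBiweight(4.685)).fit()
        fitted = np.polynomial.polynomial.polyval(t, coeffs)
        np.testing.assert_allclose(fitted, rlm.fittedvalues, atol=0.15)
        assert np.all(rlm.weights[out_idx] < 0.1)

    def test_constant_response(self, cfg):
        x = np.arange(30, dtype=float)
        coeffs, _, _ = fit_rwls_poly(x, np.full(30, 7.0), 5, cfg)
        t = np.linspace(0, 1, 50)
        vals = np.polynomial.polynomial.polyval(t, coeffs)
        np.testing.assert_allclose(vals, 7.0, atol=1e-8)
        deriv = np.polynomial.polynomial.polyval(
            t, np.polynomial.polynomial.polyder(coeffs))
        np.testing.assert_allclose(deriv, 0.0, atol=1e-6)

    def test_too_few_points(self, cfg):
        with pytest.raises(ValidationError):
            fit_rwls_poly(np.arange(5.0), np.arange(5.0), 10, cfg)

    def test_duplicate_x_rejected(self, cfg):
        x = np.array([0.0, 1.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValidationError):
            fit_rwls_poly(x, x, 4, cfg)


def ramp_plateau_series(n=200, knee_frac=0.5, noise=0.0, seed=0, kind="paw"):
    rng = np.random.default_rng(seed)
    x = np.arange(n, dtype=float) * 180
    knee = knee_frac * x[-1]
    y = np.where(x < knee, 25 * x / knee, 25.0) + rng.normal(0, noise, n)
    return BreathSeries(x, y, kind)


class TestPlateauModel:
    def test_y_scale_normalizes_to_unit_max(self, cfg):
        model = build_plateau_model(ramp_plateau_series(), cfg)
        assert model.y_scale == pytest.approx(25.0)
        assert np.max(np.abs(model.value(ramp_plateau_series().x))) <= 25.5

    def test_exact_polynomial_gives_zero_error_poly(self, cfg):
        x = np.arange(50, dtype=float)
        t = x / x.max()
        y = 3 + 2 * t - 5 * t**2  # degree 2 <= K: fit is exact
        model = build_plateau_model(BreathSeries(x, y, "paw"), cfg)
        tt = np.linspace(0, 1, 100)
        err = np.polynomial.polynomial.polyval(tt, model.err_coeffs)
        np.testing.assert_allclose(err, 0.0, atol=1e-3)

    def test_noiseless_ramp_plateau_small_error_poly(self, cfg):
        model = build_plateau_model(ramp_plateau_series(), cfg)
        tt = np.linspace(0, 1, 200)
        err = np.polynomial.polynomial.polyval(tt, model.err_coeffs)
        assert np.max(np.abs(err)) <= 0.25  # sqrt-residual scale of the knee misfit

    def test_series_too_short(self, cfg):
        with pytest.raises(ValidationError):
            build_plateau_model(BreathSeries(np.arange(5.0), np.ones(5), "vt"), cfg)


class TestInfoFunction:
    def test_nonnegative_everywhere(self, cfg):
        model = build_plateau_model(ramp_plateau_series(noise=0.5), cfg)
        info = info_function(model)
        rng = np.random.default_rng(0)
        lo, hi = model.domain
        assert np.all(info(rng.uniform(lo, hi, 100)) >= 0)

    def test_plateau_info_below_rise_info(self, cfg):
        series = ramp_plateau_series(knee_frac=0.5)
        info = info_function(build_plateau_model(series, cfg))
        rise_mid = series.x[-1] * 0.25
        plateau_mid = series.x[-1] * 0.75
        assert info(plateau_mid) < info(rise_mid)

    def test_constant_series_info_near_zero(self, cfg):
        x = np.arange(60, dtype=float)
        info = info_function(build_plateau_model(BreathSeries(x, np.full(60, 4.0), "vt"), cfg))
        assert float(info(30.0)) == pytest.approx(0.0, abs=1e-8)

    def test_out_of_domain_raises(self, cfg):
        model = build_plateau_model(ramp_plateau_series(), cfg)
        info = info_function(model)
        with pytest.raises(DomainError):
            info(model.domain[1] + 1.0)

    def test_invariant_under_time_shift(self, cfg):
        series = ramp_plateau_series(noise=0.3, seed=4)
        shifted = BreathSeries(series.x + 50_000, series.y, series.kind)
        info_a = info_function(build_plateau_model(series, cfg))
        info_b = info_function(build_plateau_model(shifted, cfg))
        probe = np.linspace(series.x[0], series.x[-1], 50)
        np.testing.assert_allclose(info_a(probe), info_b(probe + 50_000), rtol=1e-6)
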