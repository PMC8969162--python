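"""Gradient regression: finite differences, analysis band, robust rejection,
line fit, and recovery on simulated transport fields."""

import warnings

import numpy as np
import pytest
from sklearn.base import clone

from kymoflow import (
    AdvectionDiffusionRegressor,
    SyntheticScenario,
    band_mask,
    estimate,
    finite_differences,
    fit_line,
    remove_outliers,
    stahel_donoho_outlyingness,
)
from kymoflow.adfit import StahelDonohoOutlierDetector, apply_band
from kymoflow.containers import Kymograph, TimeWindow

from conftest import field_kymograph


def polynomial_kymograph(v=0.2, k=0.3, n=50, dr=1.0, dt=1.0):
    """φ(r,t) = (r − v t)² + 2 k t: quadratic in r, so every second difference
    is exact and the discretized balance holds pixel by pixel."""
    r = np.arange(n) * dr
    t = np.arange(n) * dt
    phi = (r[:, None] - v * t[None, :]) ** 2 + 2 * k * t[None, :]
    ky = Kymograph(
        values=phi, dr=dr, dt=dt, window=TimeWindow(0.0, float(t[-1])), normalized=True
    )
    ky.background_subtracted = True
    return ky


class TestFiniteDifferences:
    def test_constant_field_has_no_finite_samples(self):
        ky = polynomial_kymograph()
        ky.values = np.full_like(ky.values, 2.0)
        s = finite_differences(ky)
        assert s.finite.sum() == 0

    def test_linear_ramp_has_no_finite_samples(self):
        ky = polynomial_kymograph()
        ky.values = np.tile(np.arange(50.0)[:, None], (1, 50))
        s = finite_differences(ky)
        assert s.finite.sum() == 0

    def test_polynomial_field_satisfies_shifted_balance_exactly(self):
        v, k = 0.2, 0.3
        s = finite_differences(polynomial_kymograph(v, k))
        f = s.finite
        expected_intercept = k + v * (1 + v) / 2.0
        resid = s.a_prime[f] - (v * s.b_prime[f] + expected_intercept)
        assert np.abs(resid).max() < 1e-9

    def test_too_small_kymograph_rejected(self):
        ky = polynomial_kymograph(n=2)
        with pytest.raises(ValueError, match="too small"):
            finite_differences(ky)

    def test_scale_invariance_of_ratios(self, rng):
        ky = polynomial_kymograph()
        ky.values = ky.values + 0.01 * rng.random(ky.values.shape)
        s1 = finite_differences(ky)
        ky2 = ky.copy()
        ky2.values = ky2.values * 37.5
        s2 = finite_differences(ky2, c_min=1e-4 * 37.5)
        f = s1.finite & s2.finite
        assert np.allclose(s1.a_prime[f], s2.a_prime[f])
        assert np.allclose(s1.b_prime[f], s2.b_prime[f])

    def test_grid_covariance_pixels_vs_microns(self):
        """Expressing Δr in pixels instead of µm rescales v by the pixel size
        and k by its square."""
        scale = 0.41
        s_um = finite_differences(polynomial_kymograph(v=0.2, k=0.3, dr=1.0))
        fit_um = fit_line(s_um)
        s_px = finite_differences(
            polynomial_kymograph(v=0.2 / scale, k=0.3 / scale**2, dr=1.0 / scale),
            c_min=1e-4 * scale**2,
        )
        fit_px = fit_line(s_px)
        assert fit_px.v * scale == pytest.approx(fit_um.v, rel=1e-9)


class TestBandMask:
    def test_band_endpoints(self):
        r_eel, t_end = 41.0, 100.0
        assert band_mask(np.array([0.0]), np.array([0.0]), r_eel, t_end)[0]
        assert not band_mask(np.array([2.05]), np.array([0.0]), r_eel, t_end)[0]
        mid = band_mask(np.linspace(0, r_eel, 21), np.full(21, t_end / 2), r_eel, t_end)
        assert mid.all()
        end = band_mask(np.array([r_eel, r_eel - 2.0]), np.array([t_end, t_end]), r_eel, t_end)
        assert end.tolist() == [True, False]

    def test_nonpositive_t_end_rejected(self):
        with pytest.raises(ValueError):
            band_mask(np.zeros(1), np.zeros(1), 41.0, 0.0)


def _outlyingness_oracle(X):
    """Brute-force Stahel–Donoho outlyingness over all point-pair directions."""
    n = len(X)
    out = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = X[i] - X[j]
            norm = np.linalg.norm(d)
            if norm == 0:
                continue
            u = d / norm
            proj = X @ u
            med = np.median(proj)
            dev = np.abs(proj - med)
            mad = 1.4826 * np.median(dev)
            if mad > 0:
                score = dev / mad
            else:
                score = np.where(dev > 0, np.inf, 0.0)
            out = np.maximum(out, score)
    return out


class TestStahelDonoho:
    def test_matches_bruteforce_oracle_on_random_clouds(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((20, 2))
            got = stahel_donoho_outlyingness(X)
            want = _outlyingness_oracle(X)
            finite = np.isfinite(want)
            assert np.allclose(got[finite], want[finite])
            assert np.array_equal(np.isfinite(got), finite)

    def test_collinear_points_keep_everyone(self):
        x = np.linspace(0, 1, 20)
        X = np.column_stack([x, 0.5 * x + 0.2])
        det = StahelDonohoOutlierDetector().fit(X)
        assert (det.predict(X) == 1).all()

    def test_displaced_point_is_the_only_exclusion(self):
        x = np.linspace(0, 1, 20)
        X = np.column_stack([x, 0.5 * x + 0.2])
        # displace one point far off the line, orthogonally
        off = np.vstack([X, [0.5, 0.5 * 0.5 + 0.2 + 10.0]])
        det = StahelDonohoOutlierDetector()
        labels = det.fit_predict(off)
        assert labels[-1] == -1
        assert (labels[:-1] == 1).all()
        oracle = _outlyingness_oracle(off)
        assert np.array_equal(oracle > det.threshold_, labels == -1)

    def test_tiny_sample_passes_through_with_warning(self):
        ky = polynomial_kymograph(n=4)
        s = finite_differences(ky)
        s.finite[:] = False
        s.finite[:3] = True
        with pytest.warns(UserWarning, match="skipping outlier rejection"):
            out = remove_outliers(s)
        assert out.inlier.all()

    def test_detector_is_deterministic_given_seed(self, rng):
        X = rng.standard_normal((800, 2))  # beyond the exact-search cap
        a = StahelDonohoOutlierDetector(random_state=5).fit(X).outlyingness_
        b = StahelDonohoOutlierDetector(random_state=5).fit(X).outlyingness_
        assert np.array_equal(a, b)


class TestFitLine:
    def test_exact_line_recovered(self, rng):
        x = rng.uniform(-2, 2, size=30)
        y = 0.5 * x + 0.2
        ky = polynomial_kymograph(n=6)
        s = finite_differences(ky)
        s.b_prime = x
        s.a_prime = y
        s.finite = np.ones(len(x), bool)
        s.in_band = np.ones(len(x), bool)
        s.inlier = np.ones(len(x), bool)
        s.r = np.zeros(len(x))
        s.t = np.zeros(len(x))
        fit = fit_line(s)
        assert fit.v == pytest.approx(0.5)
        assert fit.k == pytest.approx(0.2)
        assert fit.r_value == pytest.approx(1.0)

    def test_polynomial_field_fit_slope_exact(self):
        s = finite_differences(polynomial_kymograph(0.2, 0.3))
        apply_band(s, r_eel=50.0, t_end=49.0)
        remove_outliers(s)
        fit = fit_line(s)
        assert fit.v == pytest.approx(0.2, abs=1e-10)
        assert fit.k == pytest.approx(0.42, abs=1e-10)

    def test_degenerate_scatter_rejected(self):
        s = finite_differences(polynomial_kymograph(n=6))
        s.b_prime = np.full(8, 1.0)
        s.a_prime = np.arange(8.0)
        for name in ("finite", "in_band", "inlier"):
            setattr(s, name, np.ones(8, bool))
        s.r = np.zeros(8)
        s.t = np.zeros(8)
        with pytest.raises(ValueError, match="degenerate"):
            fit_line(s)


class TestAdvectionDiffusionRegressor:
    def test_sklearn_contract(self, rng):
        x = rng.uniform(-1, 1, 50)[:, None]
        y = 0.3 * x[:, 0] + 0.1 + rng.normal(0, 0.01, 50)
        reg = AdvectionDiffusionRegressor(random_state=0)
        cloned = clone(reg)
        cloned.fit(x, y)
        assert cloned.velocity_ == pytest.approx(0.3, abs=0.02)
        assert cloned.diffusion_ == pytest.approx(0.1, abs=0.02)
        pred = cloned.predict(np.array([[0.0], [1.0]]))
        assert pred[0] == pytest.approx(cloned.intercept_)
        params = cloned.get_params()
        assert params["random_state"] == 0

    def test_planted_outlier_rejected_before_fit(self, rng):
        x = rng.uniform(-1, 1, 40)
        y = 0.3 * x + 0.1
        x = np.append(x, 0.0)
        y = np.append(y, 50.0)
        reg = AdvectionDiffusionRegressor().fit(x[:, None], y)
        assert not reg.inlier_mask_[-1]
        assert reg.velocity_ == pytest.approx(0.3, abs=1e-9)


class TestEstimateOnSimulatedFields:
    def test_velocity_recovered_within_ten_percent(self):
        sc = SyntheticScenario(v=0.4, k=0.4)
        fit = estimate(field_kymograph(sc))
        assert abs(fit.v - 0.4) / 0.4 < 0.10

    def test_pure_diffusion_velocity_near_zero(self):
        sc = SyntheticScenario(v=0.0, k=0.4, length=20.5, duration=1500.0)
        fit = estimate(field_kymograph(sc))
        assert abs(fit.v) < 0.02

    def test_constant_kymograph_raises(self):
        ky = polynomial_kymograph()
        ky.values = np.ones_like(ky.values)
        with pytest.raises(ValueError):
            estimate(ky)

    def test_increasing_velocity_monotone_in_estimates(self, pressure_series):
        vs = sorted(pressure_series)
        vhats = [pressure_series[v].fit.v for v in vs]
        assert all(b > a for a, b in zip(vhats, vhats[1:]))
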