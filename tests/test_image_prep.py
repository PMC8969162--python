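"""Drift compensation, arc fitting, polar unwrapping, temporal resampling."""

import numpy as np
import pytest
from scipy import ndimage

from kymoflow import ImageStack, correct_drift, fit_arc, resample_time, unwrap_polar


def _stack(frames, timestamps=None):
    frames = np.asarray(frames, dtype=float)
    if timestamps is None:
        timestamps = np.arange(frames.shape[0], dtype=float)
    return ImageStack(frames=frames, timestamps=timestamps)


def _integer_shift_oracle(ref, frame, max_shift=6):
    """Exhaustive search for the integer shift maximizing plain correlation."""
    best, best_val = (0, 0), -np.inf
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            shifted = np.roll(frame, (dy, dx), axis=(0, 1))
            val = np.sum(ref * shifted)
            if val > best_val:
                best_val, best = val, (dy, dx)
    return best


class TestCorrectDrift:
    def test_zero_drift_gives_zero_displacements(self, rng):
        base = rng.random((30, 40))
        st = _stack(np.stack([base] * 3))
        _, trace = correct_drift(st)
        assert np.allclose(trace.shifts, 0.0)

    def test_recovers_injected_integer_shift(self, rng):
        base = rng.random((40, 60)) * 100
        shifted = np.roll(base, (3, -2), axis=(0, 1))
        st = _stack(np.stack([base, base, shifted]))
        out, trace = correct_drift(st)
        oracle = _integer_shift_oracle(base, shifted)
        assert tuple(trace.shifts[2]) == (-3.0, 2.0)
        assert tuple(trace.shifts[2]) == (float(oracle[0]), float(oracle[1]))
        valid = out.mask[2]
        assert np.allclose(out.frames[2][valid], base[valid])

    def test_subpixel_shift_recovered_within_half_pixel(self, rng):
        yy, xx = np.mgrid[0:60, 0:80]
        base = np.exp(-(((yy - 30) / 8.0) ** 2 + ((xx - 40) / 10.0) ** 2))
        shifted = ndimage.shift(base, (0.4, 0.0), order=3)
        st = _stack(np.stack([base, shifted]))
        _, trace = correct_drift(st, subpixel=True)
        assert abs(trace.shifts[1, 0] - (-0.4)) < 0.5
        assert abs(trace.shifts[1, 1]) < 0.5

    def test_idempotent_on_integer_shifts(self, rng):
        base = rng.random((40, 60))
        st = _stack(np.stack([base, np.roll(base, (2, 1), axis=(0, 1))]))
        once, _ = correct_drift(st)
        _, trace2 = correct_drift(once)
        assert np.allclose(trace2.shifts, 0.0)

    def test_constant_frame_raises_with_frame_index(self, rng):
        frames = np.stack([rng.random((10, 10)), np.full((10, 10), 3.0)])
        with pytest.raises(ValueError, match="frame 1"):
            correct_drift(_stack(frames))

    def test_single_frame_rejected(self, rng):
        with pytest.raises(ValueError):
            correct_drift(_stack(rng.random((1, 10, 10))))


def _three_point_circle_radius(chord, camber):
    """Circle through (-chord/2, 0), (0, camber), (chord/2, 0)."""
    pts = np.array([[-chord / 2, 0.0], [0.0, camber], [chord / 2, 0.0]])
    a = np.column_stack([2 * pts, np.ones(3)])
    b = (pts**2).sum(axis=1)
    cx, cy, c0 = np.linalg.solve(a, b)
    return float(np.sqrt(c0 + cx**2 + cy**2))


class TestFitArc:
    @pytest.mark.parametrize(
        "chord,camber,expected",
        [(200.0, 100.0, 100.0), (100.0, 10.0, 130.0), (211.97, 5.5, 1023.92)],
    )
    def test_sagitta_relation_matches_three_point_circle(self, chord, camber, expected):
        geom = fit_arc(chord, camber)
        assert geom.radius == pytest.approx(expected, rel=1e-4)
        assert geom.radius == pytest.approx(_three_point_circle_radius(chord, camber), rel=1e-12)

    def test_center_below_apex(self):
        geom = fit_arc(100.0, 10.0, apex=(50.0, 20.0))
        assert geom.center == (50.0, 20.0 + geom.radius)

    @pytest.mark.parametrize("chord,camber", [(0.0, 10.0), (100.0, -1.0)])
    def test_nonpositive_inputs_rejected(self, chord, camber):
        with pytest.raises(ValueError):
            fit_arc(chord, camber)


class TestUnwrapPolar:
    @pytest.fixture
    def geometry(self):
        return fit_arc(90.0, 8.0, apex=(50.0, 10.0))

    def test_concentric_rings_phantom_gives_identical_columns(self, geometry):
        h, w = 80, 100
        yy, xx = np.mgrid[0:h, 0:w]
        rho = np.hypot(xx - geometry.center[0], yy - geometry.center[1])
        img = np.sin(rho / 3.0)
        st = _stack(img[None].repeat(2, axis=0))
        out = unwrap_polar(st, geometry, geometry.radius - 30, geometry.radius + 5)
        rows_ok = out.mask[0].all(axis=1)
        assert rows_ok.sum() > 20
        spread = np.ptp(out.frames[0][rows_ok], axis=1)
        assert spread.max() < 0.02 * np.ptp(img)

    def test_bright_arc_lands_on_single_flat_row(self, geometry):
        h, w = 80, 100
        yy, xx = np.mgrid[0:h, 0:w]
        rho = np.hypot(xx - geometry.center[0], yy - geometry.center[1])
        target = geometry.radius - 12.0
        img = np.exp(-((rho - target) ** 2) / 0.5)
        st = _stack(img[None].repeat(2, axis=0))
        r_min = geometry.radius - 30
        out = unwrap_polar(st, geometry, r_min, geometry.radius + 5)
        peak_rows = out.frames[0].argmax(axis=0)
        expected_row = (target - r_min) / st.pixel_size_r
        # ±1 px plus the sub-pixel offset of the row grid
        assert np.all(np.abs(peak_rows - expected_row) <= 1.5)

    def test_uniform_image_stays_uniform(self, geometry):
        st = _stack(np.full((2, 80, 100), 5.0))
        out = unwrap_polar(st, geometry, geometry.radius - 30, geometry.radius + 5)
        assert np.allclose(out.frames[0][out.mask[0]], 5.0)

    def test_round_trip_rewrap_reproduces_smooth_phantom(self, geometry):
        h, w = 80, 100
        yy, xx = np.mgrid[0:h, 0:w]
        rho = np.hypot(xx - geometry.center[0], yy - geometry.center[1])
        phi = np.arctan2(xx - geometry.center[0], geometry.center[1] - yy)
        img = np.sin(rho / 5.0) + 0.3 * np.cos(3 * phi)
        st = _stack(img[None].repeat(2, axis=0))
        r_min, r_max = geometry.radius - 30, geometry.radius + 5
        out = unwrap_polar(st, geometry, r_min, r_max)
        # inverse map: for each source pixel inside the sampled annulus,
        # look up the unwrapped image at (radius, angle)
        dtheta = st.pixel_size_theta / geometry.radius
        n_theta = out.frame_shape[1]
        row = (rho - r_min) / st.pixel_size_r
        col = phi / dtheta + (n_theta - 1) / 2.0
        inside = (row >= 0) & (row <= out.frame_shape[0] - 1) & (col >= 0) & (col <= n_theta - 1)
        rewrapped = ndimage.map_coordinates(
            out.frames[0], np.stack([row[inside], col[inside]]), order=1
        )
        err = np.abs(rewrapped - img[inside])
        assert err.mean() < 0.02 * np.ptp(img)

    def test_out_of_extent_range_rejected(self, geometry):
        st = _stack(np.random.default_rng(0).random((2, 80, 100)))
        with pytest.raises(ValueError, match="exceeds source extent"):
            unwrap_polar(st, geometry, geometry.center[1] + 1, geometry.center[1] + 40)


class TestResampleTime:
    def test_existing_timestamp_returned_exactly(self, rng):
        frames = rng.random((3, 8, 8))
        st = _stack(frames, timestamps=np.array([0.0, 1.0, 2.0]))
        out = resample_time(st, 1.0)
        assert np.array_equal(out.frames, frames)

    def test_linear_interpolation_between_frames(self):
        frames = np.array([0.0, 27.0])[:, None, None] * np.ones((2, 4, 4))
        st = _stack(frames, timestamps=np.array([0.0, 2.7]))
        out = resample_time(st, 1.0)
        assert out.frames[1, 0, 0] == pytest.approx(27.0 / 2.7)
        assert np.allclose(out.timestamps, [0.0, 1.0, 2.0])

    def test_single_frame_rejected(self, rng):
        with pytest.raises(ValueError):
            resample_time(_stack(rng.random((1, 4, 4))), 1.0)

    def test_monotone_series_stays_monotone(self, rng):
        raw = np.sort(rng.random((6, 5, 5)), axis=0)
        st = _stack(raw, timestamps=np.array([0.0, 2.9, 5.7, 8.3, 11.6, 14.0]))
        out = resample_time(st, 1.0)
        assert np.all(np.diff(out.frames, axis=0) >= -1e-12)

    def test_timestamps_rebased_to_zero(self, rng):
        st = _stack(rng.random((3, 4, 4)), timestamps=np.array([5.0, 8.1, 11.3]))
        out = resample_time(st, 1.0)
        assert out.timestamps[0] == 0.0
        assert out.timestamps[-1] <= 11.3 - 5.0
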