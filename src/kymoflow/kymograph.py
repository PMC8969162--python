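"""Kymograph construction and normalization.

From the flattened, 1-second stack: detect the analysis window from the mean
wall intensity, reslice into an r–t map averaged over θ, crop to the media,
block-average radially, subtract the arrival-time background and normalize
each row by its plateau value so intensity can stand in for dye concentration.
"""

from __future__ import annotations

import numpy as np

from .containers import ImageStack, Kymograph, TimeWindow

__all__ = [
    "mean_region_intensity",
    "detect_start_time",
    "detect_end_time",
    "detect_time_window",
    "build_kymograph",
    "crop_media",
    "downsample",
    "subtract_background",
    "normalize",
    "build_normalized_kymograph",
]

DEFAULT_ALPHA = 0.005  # fraction of dynamic range marking dye arrival
DEFAULT_T_MA = 10.0    # moving-average window, s
DEFAULT_BETA = 1.0     # plateau threshold, raw intensity units per second


def mean_region_intensity(stack: ImageStack, region_mask: np.ndarray) -> np.ndarray:
    """Per-frame mean intensity over the wall region (valid pixels only)."""
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != stack.frame_shape:
        raise ValueError("region mask must match frame shape")
    if not region_mask.any():
        raise ValueError("region mask is empty")
    sel = stack.mask & region_mask[None, :, :]
    counts = sel.sum(axis=(1, 2))
    if np.any(counts == 0):
        raise ValueError("a frame has no valid pixel inside the region mask")
    return np.where(sel, stack.frames, 0.0).sum(axis=(1, 2)) / counts


def detect_start_time(series: np.ndarray, alpha: float = DEFAULT_ALPHA) -> int:
    """First time the mean intensity rises ``alpha`` of its range above the minimum.

    The series is sampled at 1-second steps, so the returned index doubles as
    seconds.  The comparison is inclusive; ties resolve to the earliest time.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("series too short")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    i_min, i_max = series.min(), series.max()
    if i_max <= i_min:
        raise ValueError("constant intensity series: arrival threshold undefined")
    threshold = (i_max - i_min) * alpha
    hits = np.nonzero(series - i_min >= threshold)[0]
    return int(hits[0])


def moving_average(series: np.ndarray, t_ma: int) -> np.ndarray:
    """Trailing mean over the last ``t_ma`` samples inclusive of the current one.

    Entries before index ``t_ma - 1`` are undefined (NaN).
    """
    series = np.asarray(series, dtype=float)
    t_ma = int(t_ma)
    if t_ma < 1:
        raise ValueError("t_ma must be >= 1")
    out = np.full(series.shape, np.nan)
    if len(series) >= t_ma:
        kernel = np.ones(t_ma) / t_ma
        out[t_ma - 1:] = np.convolve(series, kernel, mode="valid")
    return out


def detect_end_time(
    series: np.ndarray,
    t_start: int,
    t_ma: float = DEFAULT_T_MA,
    beta: float = DEFAULT_BETA,
) -> int:
    """First time after ``t_start`` the smoothed intensity climbs less than ``beta``.

    The trailing ``t_ma``-second moving average Ī is differenced step to step;
    ``t_end`` is the first t > t_start with both Ī(t) and Ī(t-1) defined and
    Ī(t) - Ī(t-1) < beta.
    """
    series = np.asarray(series, dtype=float)
    t_ma = int(t_ma)
    if len(series) <= t_start + t_ma:
        raise ValueError("series too short after t_start for the moving average")
    smoothed = moving_average(series, t_ma)
    diffs = np.diff(smoothed)  # diffs[t-1] = Ī(t) - Ī(t-1)
    for t in range(max(int(t_start) + 1, t_ma), len(series)):
        if np.isfinite(diffs[t - 1]) and diffs[t - 1] < beta:
            return int(t)
    raise ValueError("no plateau reached: moving-average increments never fell below beta")


def detect_time_window(
    series: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    t_ma: float = DEFAULT_T_MA,
    beta: float = DEFAULT_BETA,
) -> TimeWindow:
    """Detect both ends of the analysis window from one intensity series."""
    series = np.asarray(series, dtype=float)
    t_start = detect_start_time(series, alpha)
    t_end = detect_end_time(series, t_start, t_ma, beta)
    return TimeWindow(
        t_start=float(t_start),
        t_end=float(t_end),
        alpha=alpha,
        t_ma=t_ma,
        beta=beta,
        i_min=float(series.min()),
        i_max=float(series.max()),
    )


def build_kymograph(stack: ImageStack, window: TimeWindow) -> Kymograph:
    """Reslice the stack into the r–t plane and average over θ.

    Uses the frames between ``t_start`` and ``t_end`` inclusive; each
    kymograph pixel is the mean over the circumferential axis of the valid
    pixels at that radius and time.
    """
    rel = stack.timestamps - stack.timestamps[0]
    dt_steps = np.diff(rel)
    if len(dt_steps) == 0:
        raise ValueError("stack has a single frame")
    dt = float(dt_steps[0])
    if not np.allclose(dt_steps, dt):
        raise ValueError("stack must be uniformly sampled in time (resample first)")
    j0 = int(round(window.t_start / dt))
    j1 = int(round(window.t_end / dt))
    if not (0 <= j0 < j1 < stack.n_frames):
        raise ValueError("analysis window outside the stack time range")
    frames = stack.frames[j0 : j1 + 1]
    mask = stack.mask[j0 : j1 + 1]
    counts = mask.sum(axis=2)  # (n_t, n_r)
    sums = np.where(mask, frames, 0.0).sum(axis=2)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    values = means.T  # (n_r, n_t)
    pix_mask = (counts.T > 0)
    values = np.where(pix_mask, values, 0.0)
    return Kymograph(
        values=values,
        dr=stack.pixel_size_r,
        dt=dt,
        window=window,
        mask=pix_mask,
        meta=dict(stack.meta),
    )


def crop_media(kymo: Kymograph, r_iel_pixel: int, r_eel_pixel: int) -> Kymograph:
    """Keep only the media rows, half-open ``[r_iel_pixel, r_eel_pixel)``.

    The radial origin is re-zeroed at the IEL and ``r_eel`` becomes the cropped
    height in µm.
    """
    if not 0 <= r_iel_pixel < r_eel_pixel <= kymo.n_r:
        raise ValueError(
            f"invalid media bounds ({r_iel_pixel}, {r_eel_pixel}) for {kymo.n_r} rows"
        )
    out = kymo.copy()
    out.values = kymo.values[r_iel_pixel:r_eel_pixel].copy()
    out.mask = kymo.mask[r_iel_pixel:r_eel_pixel].copy()
    out.row_valid = kymo.row_valid[r_iel_pixel:r_eel_pixel].copy()
    out.r_eel = (r_eel_pixel - r_iel_pixel) * kymo.dr
    return out


def downsample(kymo: Kymograph, factor: int = 5) -> Kymograph:
    """Block-average the radial axis in non-overlapping blocks of ``factor``.

    A trailing partial block is dropped; a block with no valid pixel at a time
    point is masked there.  ``dr`` grows by the factor.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor > kymo.n_r:
        raise ValueError(f"factor {factor} exceeds kymograph height {kymo.n_r}")
    if factor == 1:
        return kymo.copy()
    n_blocks = kymo.n_r // factor
    v = kymo.values[: n_blocks * factor].reshape(n_blocks, factor, kymo.n_t)
    m = kymo.mask[: n_blocks * factor].reshape(n_blocks, factor, kymo.n_t)
    rv = kymo.row_valid[: n_blocks * factor].reshape(n_blocks, factor)
    counts = m.sum(axis=1)
    sums = np.where(m, v, 0.0).sum(axis=1)
    values = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    out = kymo.copy()
    out.values = values
    out.mask = counts > 0
    out.row_valid = rv.all(axis=1)
    out.dr = kymo.dr * factor
    out.r_eel = kymo.r_eel
    return out


def subtract_background(kymo: Kymograph) -> Kymograph:
    """Subtract each row's arrival-time value, zeroing the t_start column."""
    out = kymo.copy()
    out.values = kymo.values - kymo.values[:, [0]]
    out.background_subtracted = True
    return out


def normalize(kymo: Kymograph, epsilon: float | None = None) -> Kymograph:
    """Divide each row by its plateau (t_end) value so rows run from 0 to 1.

    Rows whose plateau magnitude is below ``epsilon`` (default 1e-6 of the
    dynamic range) are flagged invalid and excluded downstream rather than
    divided.
    """
    if not kymo.background_subtracted:
        raise ValueError("normalize expects a background-subtracted kymograph")
    denom = kymo.values[:, -1]
    if epsilon is None:
        epsilon = 1e-6 * float(np.ptp(kymo.values))
    valid = kymo.row_valid & (np.abs(denom) >= epsilon) & (epsilon > 0)
    if not valid.any():
        raise ValueError("no signal at t_end: every row's plateau value is below epsilon")
    out = kymo.copy()
    safe = np.where(valid, denom, 1.0)
    out.values = kymo.values / safe[:, None]
    out.row_valid = valid
    out.normalized = True
    return out


def build_normalized_kymograph(
    stack: ImageStack,
    r_iel_pixel: int,
    r_eel_pixel: int,
    alpha: float = DEFAULT_ALPHA,
    t_ma: float = DEFAULT_T_MA,
    beta: float = DEFAULT_BETA,
    factor: int = 5,
    epsilon: float | None = None,
) -> Kymograph:
    """Full kymograph stage: window detection through normalization.

    The wall region for window detection is the annotated media rows; the
    order of operations is crop, block-average, background subtraction,
    normalization.
    """
    region = np.zeros(stack.frame_shape, dtype=bool)
    region[r_iel_pixel:r_eel_pixel, :] = True
    series = mean_region_intensity(stack, region)
    window = detect_time_window(series, alpha=alpha, t_ma=t_ma, beta=beta)
    kymo = build_kymograph(stack, window)
    kymo = crop_media(kymo, r_iel_pixel, r_eel_pixel)
    kymo = downsample(kymo, factor)
    kymo = subtract_background(kymo)
    return normalize(kymo, epsilon)
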