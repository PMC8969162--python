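"""Raw-stack preprocessing: drift compensation, arc fitting, polar unwrapping
and temporal resampling.

The acquisition images a curved vessel wall in the r–θ plane; these steps turn
the raw stack into a drift-free, flattened stack on a uniform 1-second clock so
that a kymograph can be built by simple reslicing.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .containers import ArcGeometry, DriftTrace, ImageStack

__all__ = ["correct_drift", "fit_arc", "unwrap_polar", "resample_time"]


def correct_drift(
    stack: ImageStack,
    reference_index: int = 0,
    subpixel: bool = False,
    upsample_factor: int = 20,
) -> tuple[ImageStack, DriftTrace]:
    """Translate every frame onto the reference frame by cross-correlation.

    Whole-frame cross-correlation (no normalization) against a fixed reference
    frame; integer-pixel shifts by default, optional subpixel refinement via
    upsampled cross-correlation.  Pixels rolled in from outside the field of
    view are masked invalid so they never enter θ-averages.

    Returns the corrected stack and the trace of applied shifts
    (radial, circumferential), one row per frame, ``(0, 0)`` at the reference.
    """
    if stack.n_frames < 2:
        raise ValueError("drift correction needs at least 2 frames")
    if not 0 <= reference_index < stack.n_frames:
        raise ValueError("reference_index out of range")
    ref = stack.frames[reference_index]
    if np.ptp(ref) == 0:
        raise ValueError(f"frame {reference_index} is constant; correlation undefined")

    out = stack.copy()
    shifts = np.zeros((stack.n_frames, 2))
    for i in range(stack.n_frames):
        if i == reference_index:
            continue
        frame = stack.frames[i]
        if np.ptp(frame) == 0:
            raise ValueError(f"frame {i} is constant; correlation undefined")
        shift, _, _ = phase_cross_correlation(
            ref,
            frame,
            upsample_factor=upsample_factor if subpixel else 1,
            normalization=None,
        )
        shifts[i] = shift
        out.frames[i], out.mask[i] = _apply_shift(frame, stack.mask[i], shift)
    return out, DriftTrace(shifts=shifts, reference_index=reference_index)


def _apply_shift(
    frame: np.ndarray, mask: np.ndarray, shift: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    if np.allclose(shift, np.round(shift)):
        dy, dx = int(round(shift[0])), int(round(shift[1]))
        shifted = np.roll(frame, (dy, dx), axis=(0, 1))
        new_mask = np.roll(mask, (dy, dx), axis=(0, 1))
        # pixels wrapped around carry no information
        if dy > 0:
            new_mask[:dy, :] = False
        elif dy < 0:
            new_mask[dy:, :] = False
        if dx > 0:
            new_mask[:, :dx] = False
        elif dx < 0:
            new_mask[:, dx:] = False
        return shifted, new_mask
    shifted = ndimage.shift(frame, shift, order=1, mode="constant", cval=0.0)
    valid = ndimage.shift(mask.astype(float), shift, order=1, mode="constant", cval=0.0)
    return shifted, valid > 0.999


def fit_arc(chord: float, camber: float, apex: tuple[float, float] = (0.0, 0.0)) -> ArcGeometry:
    """Recover the lamina circle from its chord and camber (sagitta relation).

    ``apex`` is the arc apex in image coordinates (x, y), y increasing
    downward; the center lands on the symmetry axis at distance ``radius``
    below the apex (toward the lumen).
    """
    if chord <= 0 or camber <= 0:
        raise ValueError("chord and camber must be positive")
    radius = camber / 2.0 + chord**2 / (8.0 * camber)
    center = (apex[0], apex[1] + radius)
    return ArcGeometry(chord=chord, camber=camber, radius=radius, center=center)


def unwrap_polar(
    stack: ImageStack,
    geometry: ArcGeometry,
    r_min: float,
    r_max: float,
    theta_span: float | None = None,
) -> ImageStack:
    """Flatten the curved wall: resample each frame along constant-radius arcs.

    Output rows run from radius ``r_min`` (lumen side) to ``r_max`` (outward)
    in steps of ``pixel_size_r`` around the fitted circle center — equivalent
    to rotating an analysis line about the center and recording the intensity
    along it.  Column spacing is one pixel of arc length at the fitted lamina
    radius, so the flattened image keeps the acquisition resolution on both
    axes.  Intensities are bilinearly interpolated; samples falling outside the
    source grid are masked invalid.
    """
    if r_min <= 0 or r_max <= r_min:
        raise ValueError("need 0 < r_min < r_max")
    h, w = stack.frame_shape
    cy = geometry.center[1]
    if r_max > cy:
        raise ValueError(
            f"radial range [{r_min}, {r_max}] exceeds source extent: rows above the "
            f"image top (radius > {cy:.2f}) would be clipped"
        )

    dr = stack.pixel_size_r
    radii = np.arange(r_min, r_max + dr / 2, dr)
    if theta_span is None:
        theta_span = 2.0 * np.arcsin(min(1.0, geometry.chord / (2.0 * geometry.radius)))
    dtheta = stack.pixel_size_theta / geometry.radius
    n_theta = max(2, int(np.floor(theta_span / dtheta)) + 1)
    angles = (np.arange(n_theta) - (n_theta - 1) / 2.0) * dtheta

    cx = geometry.center[0]
    rho, phi = np.meshgrid(radii, angles, indexing="ij")
    ys = cy - rho * np.cos(phi)
    xs = cx + rho * np.sin(phi)
    coords = np.stack([ys.ravel(), xs.ravel()])

    inside = (ys >= 0) & (ys <= h - 1) & (xs >= 0) & (xs <= w - 1)
    if not inside.any():
        raise ValueError(
            f"radial range [{r_min}, {r_max}] exceeds source extent: no sample lands inside"
        )

    out_frames = np.empty((stack.n_frames, len(radii), n_theta))
    out_mask = np.empty((stack.n_frames, len(radii), n_theta), dtype=bool)
    for i in range(stack.n_frames):
        vals = ndimage.map_coordinates(
            stack.frames[i], coords, order=1, mode="constant", cval=0.0
        ).reshape(rho.shape)
        src_valid = ndimage.map_coordinates(
            stack.mask[i].astype(float), coords, order=1, mode="constant", cval=0.0
        ).reshape(rho.shape)
        out_frames[i] = vals
        out_mask[i] = inside & (src_valid > 0.999)

    meta = dict(stack.meta)
    meta.update({"unwrap_r_min": float(radii[0]), "unwrap_r_max": float(radii[-1])})
    return ImageStack(
        frames=out_frames,
        timestamps=stack.timestamps.copy(),
        pixel_size_r=stack.pixel_size_r,
        pixel_size_theta=stack.pixel_size_theta,
        mask=out_mask,
        meta=meta,
    )


def resample_time(stack: ImageStack, target_interval: float = 1.0) -> ImageStack:
    """Resample the stack onto a uniform clock by frame-pair interpolation.

    Output timestamps are 0, Δ, 2Δ, … rebased to the first frame; each output
    frame is the linear blend of the two bracketing acquisitions.  No
    extrapolation: the output clock stops at the last acquired frame.
    """
    if stack.n_frames < 2:
        raise ValueError("temporal resampling needs at least 2 frames")
    if target_interval <= 0:
        raise ValueError("target_interval must be positive")
    rel = stack.timestamps - stack.timestamps[0]
    n_out = int(np.floor(rel[-1] / target_interval + 1e-9)) + 1
    queries = np.arange(n_out) * target_interval
    if queries[-1] > rel[-1] + 1e-9:
        raise ValueError("resampling query outside the acquired time range")

    out_frames = np.empty((n_out, *stack.frame_shape))
    out_mask = np.empty((n_out, *stack.frame_shape), dtype=bool)
    for j, q in enumerate(queries):
        hi = int(np.searchsorted(rel, q, side="left"))
        if hi < len(rel) and abs(rel[hi] - q) < 1e-9:
            out_frames[j] = stack.frames[hi]
            out_mask[j] = stack.mask[hi]
            continue
        lo = hi - 1
        w = (q - rel[lo]) / (rel[hi] - rel[lo])
        out_frames[j] = (1.0 - w) * stack.frames[lo] + w * stack.frames[hi]
        out_mask[j] = stack.mask[lo] & stack.mask[hi]

    return ImageStack(
        frames=out_frames,
        timestamps=queries,
        pixel_size_r=stack.pixel_size_r,
        pixel_size_theta=stack.pixel_size_theta,
        mask=out_mask,
        meta=dict(stack.meta),
    )
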