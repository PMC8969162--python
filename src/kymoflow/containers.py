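"""Domain containers shared across the pipeline.

All physical quantities are in micrometres and seconds.  Radial coordinates
increase from the lumen (intimal side) outward; time is rebased so the first
retained frame of a processed object sits at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

PIXEL_SIZE_UM = 0.41  # acquisition resolution, µm/pixel, both axes


@dataclass
class ImageStack:
    """Time-lapse stack indexed (time, radial, circumferential).

    ``mask`` marks pixels that carry valid intensity; pixels rolled in from
    outside the field of view by drift correction, or sampled outside the
    source grid by polar unwrapping, are masked out and excluded from every
    later average.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    pixel_size_r: float = PIXEL_SIZE_UM
    pixel_size_theta: float = PIXEL_SIZE_UM
    mask: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (t, r, theta), got {self.frames.ndim}-D")
        if self.timestamps.shape != (self.frames.shape[0],):
            raise ValueError("timestamps must have one entry per frame")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.pixel_size_r <= 0 or self.pixel_size_theta <= 0:
            raise ValueError("pixel sizes must be positive")
        if self.mask is None:
            self.mask = np.ones(self.frames.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.frames.shape:
                raise ValueError("mask must match frames shape")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def copy(self) -> "ImageStack":
        return ImageStack(
            frames=self.frames.copy(),
            timestamps=self.timestamps.copy(),
            pixel_size_r=self.pixel_size_r,
            pixel_size_theta=self.pixel_size_theta,
            mask=self.mask.copy(),
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class ArcGeometry:
    """Circle recovered from the chord and camber of a traced elastic lamina.

    The sagitta relation ties the three lengths together:
    ``radius = camber/2 + chord**2 / (8*camber)``.  ``center`` is expressed in
    the image frame (x, y) with y increasing downward, placed on the arc's axis
    of symmetry at distance ``radius`` below the apex.
    """

    chord: float
    camber: float
    radius: float
    center: tuple[float, float]

    def __post_init__(self) -> None:
        if self.chord <= 0 or self.camber <= 0:
            raise ValueError("chord and camber must be positive")
        expected = self.camber / 2.0 + self.chord**2 / (8.0 * self.camber)
        if not np.isclose(self.radius, expected, rtol=1e-6):
            raise ValueError(
                f"radius {self.radius} inconsistent with chord/camber (expected {expected})"
            )


@dataclass
class DriftTrace:
    """Per-frame translation applied during drift compensation, in pixels."""

    shifts: np.ndarray  # (n_frames, 2) — (radial, circumferential)
    reference_index: int

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError("shifts must be (n_frames, 2)")
        if not np.allclose(self.shifts[self.reference_index], 0.0):
            raise ValueError("reference frame displacement must be (0, 0)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.shifts)),
                "dr": self.shifts[:, 0],
                "dtheta": self.shifts[:, 1],
            }
        )


@dataclass
class TimeWindow:
    """Analysis window on the resampled (1 s) clock.

    ``t_start`` is when the mean wall intensity first rises a fraction ``alpha``
    of its dynamic range above the minimum; ``t_end`` is when the trailing
    ``t_ma``-second moving average first climbs by less than ``beta`` per step.
    """

    t_start: float
    t_end: float
    alpha: float = 0.005
    t_ma: float = 10.0
    beta: float = 1.0
    i_min: float | None = None
    i_max: float | None = None

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("t_start must precede t_end")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.t_ma < 1:
            raise ValueError("t_ma must be at least 1 s")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class Kymograph:
    """θ-averaged radius–time intensity map.

    ``values`` is indexed (radial, time); column ``j`` sits at ``t_start + j*dt``
    on the resampled clock, row ``i`` at ``r = i*dr`` from the current radial
    origin (the IEL once the media is cropped).  ``row_valid`` marks rows that
    survive the normalization guard and feed the gradient regression.
    """

    values: np.ndarray
    dr: float
    dt: float
    window: TimeWindow
    r_eel: float | None = None
    mask: np.ndarray | None = None
    row_valid: np.ndarray | None = None
    background_subtracted: bool = False
    normalized: bool = False
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("kymograph values must be 2-D (radial, time)")
        if self.dr <= 0 or self.dt <= 0:
            raise ValueError("dr and dt must be positive")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask must match values shape")
        if self.row_valid is None:
            self.row_valid = np.ones(self.values.shape[0], dtype=bool)
        else:
            self.row_valid = np.asarray(self.row_valid, dtype=bool)
            if self.row_valid.shape != (self.values.shape[0],):
                raise ValueError("row_valid must have one entry per row")
        if self.r_eel is None:
            self.r_eel = self.values.shape[0] * self.dr
        if self.r_eel <= 0:
            raise ValueError("r_eel must be positive")

    @property
    def n_r(self) -> int:
        return self.values.shape[0]

    @property
    def n_t(self) -> int:
        return self.values.shape[1]

    @property
    def r(self) -> np.ndarray:
        """Radial coordinate of each row, µm from the current origin."""
        return np.arange(self.n_r) * self.dr

    @property
    def t(self) -> np.ndarray:
        """Time of each column, seconds from t_start."""
        return np.arange(self.n_t) * self.dt

    def copy(self) -> "Kymograph":
        return replace(
            self,
            values=self.values.copy(),
            mask=self.mask.copy(),
            row_valid=self.row_valid.copy(),
            meta=dict(self.meta),
        )


@dataclass
class GradientSampleSet:
    """Per-pixel finite-difference coefficients of the transport balance.

    For every interior kymograph pixel: ``a`` is the forward time derivative
    (1/s), ``b`` the forward radial derivative (1/µm), ``c`` the central second
    radial derivative (1/µm²); the regression coordinates are ``a' = a/c``
    (µm²/s) and ``b' = -b/c`` (µm).  ``finite`` requires |c| above the
    curvature floor, ``in_band`` the diagonal analysis band, ``inlier``
    survival of robust outlier rejection.
    """

    r: np.ndarray
    t: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    a_prime: np.ndarray
    b_prime: np.ndarray
    finite: np.ndarray
    in_band: np.ndarray
    inlier: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.r)
        for name in ("t", "a", "b", "c", "a_prime", "b_prime", "finite", "in_band", "inlier"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} length mismatch")

    @property
    def usable(self) -> np.ndarray:
        return self.finite & self.in_band

    @property
    def retained(self) -> np.ndarray:
        return self.usable & self.inlier

    @property
    def n_plot(self) -> int:
        return int(np.count_nonzero(self.retained))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r": self.r,
                "t": self.t,
                "a": self.a,
                "b": self.b,
                "c": self.c,
                "a_prime": self.a_prime,
                "b_prime": self.b_prime,
                "finite": self.finite,
                "in_band": self.in_band,
                "inlier": self.inlier,
            }
        )


@dataclass
class FlowFit:
    """Fitted transport parameters for one kymograph (or one layer window).

    ``v`` (µm/s) is the slope and ``k`` (µm²/s) the b'-axis intercept of the
    least-squares line through the retained (b', a') scatter; ``r_value`` and
    ``p_value`` come from the Pearson correlation t-test on the same points.
    """

    v: float
    k: float
    r_value: float
    p_value: float
    n_plot: int
    label: str = "whole-media"
    d: float | None = None
    low_confidence: bool = False
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_plot < 3:
            raise ValueError("a reported fit requires at least 3 samples")
        if not -1.0 - 1e-12 <= self.r_value <= 1.0 + 1e-12:
            raise ValueError("correlation coefficient outside [-1, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def to_dict(self) -> dict[str, Any]:
        return {
            "label": self.label,
            "v": self.v,
            "k": self.k,
            "R": self.r_value,
            "p": self.p_value,
            "n_plot": self.n_plot,
            "d": self.d,
            "low_confidence": self.low_confidence,
        }


@dataclass(frozen=True)
class LayerRegion:
    """A 5–10 pixel radial window centred on an EL or SML band.

    Bounds are row indices in the native-resolution media kymograph
    (half-open, ``r_lo <= row < r_hi``); ``d`` is the window midpoint distance
    from the IEL normalized by the media thickness.
    """

    label: str
    r_lo: int
    r_hi: int
    d: float

    VALID_LABELS = ("EL1", "EL2", "EL3", "SML1", "SML2", "SML3")

    def __post_init__(self) -> None:
        if self.r_lo >= self.r_hi:
            raise ValueError("r_lo must be below r_hi")
        if not 0.0 <= self.d <= 1.0:
            raise ValueError("normalized distance d must lie in [0, 1]")

    @property
    def is_elastic_lamina(self) -> bool:
        return self.label.startswith("EL")
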