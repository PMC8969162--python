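"""Per-layer velocity estimation across the media.

The media alternates elastic laminas (EL1–3, counted from the intimal side)
and smooth-muscle-rich layers (SML1–3).  Each annotated band is a 5–10 pixel
radial window of the native-resolution media kymograph; the whole gradient
regression is rerun inside the window, and the resulting velocities are
related to the normalized depth d (0 at the IEL, 1 at the EEL).  Elastic
lamina fits are flagged low-confidence: dye binding in the laminas breaks the
intensity–concentration proportionality there, so only SML velocities are
trusted for the radial trend.
"""

from __future__ import annotations

import numpy as np

from . import kymograph as kg
from .adfit import FitConfig, estimate
from .containers import FlowFit, Kymograph, LayerRegion, TimeWindow
from .stats import pearson_test

__all__ = ["normalized_distance", "make_region", "estimate_layer", "radial_trend"]


def normalized_distance(r_mid: float, r_iel: float, r_eel: float) -> float:
    """Distance from the IEL normalized by the media thickness."""
    if not r_iel < r_eel:
        raise ValueError("r_iel must be below r_eel")
    if not r_iel <= r_mid <= r_eel:
        raise ValueError(f"r_mid {r_mid} outside the media [{r_iel}, {r_eel}]")
    return (r_mid - r_iel) / (r_eel - r_iel)


def make_region(label: str, r_lo: int, r_hi: int, n_media_rows: int, dr: float) -> LayerRegion:
    """Build a layer window from row bounds in the media kymograph.

    ``d`` is taken at the window midpoint.
    """
    r_mid = dr * (r_lo + r_hi) / 2.0
    d = normalized_distance(r_mid, 0.0, n_media_rows * dr)
    return LayerRegion(label=label, r_lo=r_lo, r_hi=r_hi, d=d)


def estimate_layer(
    kymo: Kymograph,
    region: LayerRegion,
    config: FitConfig | None = None,
    factor: int = 1,
    epsilon: float | None = None,
    alpha: float = kg.DEFAULT_ALPHA,
    t_ma: float = kg.DEFAULT_T_MA,
    beta: float = kg.DEFAULT_BETA,
) -> FlowFit:
    """Run the full estimation pipeline restricted to one layer window.

    ``kymo`` is the media kymograph at native radial resolution, before
    block-averaging, background subtraction and normalization.  The window is
    cropped out and the whole process reruns on the local image, including
    arrival/plateau detection on the window's own mean-intensity series: the
    dye sweeps past an inner lamina long before the whole wall saturates, so
    each window gets its own analysis interval (and its own diagonal band).
    If the window never plateaus before the parent kymograph ends, its end
    time falls back to the parent's.  The window must keep at least 3 rows
    after block-averaging for the second difference to exist.
    """
    if kymo.normalized or kymo.background_subtracted:
        raise ValueError("estimate_layer expects the raw (cropped) media kymograph")
    if not 0 <= region.r_lo < region.r_hi <= kymo.n_r:
        raise ValueError(f"region rows [{region.r_lo}, {region.r_hi}) outside the media")
    n_rows = (region.r_hi - region.r_lo) // factor
    if n_rows < 3:
        raise ValueError(
            f"region {region.label} keeps only {n_rows} rows after block-averaging "
            f"by {factor}; need at least 3"
        )
    sub = kg.crop_media(kymo, region.r_lo, region.r_hi)

    # local analysis window from the window's own mean-intensity trace
    counts = sub.mask.sum(axis=0)
    series = np.where(sub.mask, sub.values, 0.0).sum(axis=0) / np.maximum(counts, 1)
    t0 = kg.detect_start_time(series, alpha)
    try:
        t1 = kg.detect_end_time(series, t0, t_ma, beta)
    except ValueError:
        t1 = len(series) - 1  # window still filling when the parent ends
    if t1 - t0 < 2:
        raise ValueError(f"region {region.label}: local analysis window too short")
    j0, j1 = int(round(t0 / sub.dt)), int(round(t1 / sub.dt))
    sub.values = sub.values[:, j0 : j1 + 1]
    sub.mask = sub.mask[:, j0 : j1 + 1]
    sub.window = TimeWindow(
        t_start=kymo.window.t_start + t0, t_end=kymo.window.t_start + t1,
        alpha=alpha, t_ma=t_ma, beta=beta,
    )

    sub = kg.downsample(sub, factor)
    sub = kg.subtract_background(sub)
    sub = kg.normalize(sub, epsilon)
    fit = estimate(sub, config, label=region.label)
    fit.d = region.d
    fit.low_confidence = region.is_elastic_lamina
    return fit


def radial_trend(fits: list[FlowFit]) -> tuple[float, float]:
    """Pearson correlation (R, p) between normalized depth d and velocity v."""
    if len(fits) < 3:
        raise ValueError("need at least 3 layer fits for a radial trend")
    d = np.array([f.d for f in fits], dtype=float)
    v = np.array([f.v for f in fits], dtype=float)
    if np.any(np.isnan(d)):
        raise ValueError("every fit must carry a normalized distance d")
    res = pearson_test(d, v)
    return res.r, res.p
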