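"""End-to-end drivers tying the stages together.

``run_pipeline`` takes a raw (or already flattened) stack plus annotations and
returns the whole-media flow fit with every intermediate artifact;
``recover_scenario`` does the same starting from a synthetic scenario, which
is how recovery accuracy is measured against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import image_prep, kymograph as kg
from .adfit import FitConfig, estimate
from .containers import DriftTrace, FlowFit, ImageStack, Kymograph, LayerRegion
from .layers import estimate_layer, radial_trend
from .synthdata import SyntheticScenario, make_stack

__all__ = ["PipelineResult", "run_pipeline", "recover_scenario"]


@dataclass
class PipelineResult:
    fit: FlowFit
    kymo: Kymograph
    kymo_media: Kymograph  # cropped media, native resolution (layer input)
    window_series: np.ndarray
    drift: DriftTrace | None = None
    layer_fits: list[FlowFit] = field(default_factory=list)
    radial_r: float | None = None
    radial_p: float | None = None


def run_pipeline(
    stack: ImageStack,
    r_iel_pixel: int,
    r_eel_pixel: int,
    alpha: float = kg.DEFAULT_ALPHA,
    t_ma: float = kg.DEFAULT_T_MA,
    beta: float = kg.DEFAULT_BETA,
    factor: int = 5,
    correct_drift: bool = False,
    resample: bool = True,
    config: FitConfig | None = None,
    regions: list[LayerRegion] | None = None,
    layer_factor: int = 1,
) -> PipelineResult:
    """Stack → drift correction → 1-s resampling → kymograph → (v, k) fit.

    ``regions`` optionally adds per-layer fits and the d–v radial trend
    (computed on the SML windows, the trustworthy ones).
    """
    drift = None
    if correct_drift:
        stack, drift = image_prep.correct_drift(stack)
    if resample:
        stack = image_prep.resample_time(stack, 1.0)

    region = np.zeros(stack.frame_shape, dtype=bool)
    region[r_iel_pixel:r_eel_pixel, :] = True
    series = kg.mean_region_intensity(stack, region)
    window = kg.detect_time_window(series, alpha=alpha, t_ma=t_ma, beta=beta)
    kymo_full = kg.build_kymograph(stack, window)
    kymo_media = kg.crop_media(kymo_full, r_iel_pixel, r_eel_pixel)
    kymo = kg.downsample(kymo_media, factor)
    kymo = kg.subtract_background(kymo)
    kymo = kg.normalize(kymo)
    fit = estimate(kymo, config)

    result = PipelineResult(
        fit=fit, kymo=kymo, kymo_media=kymo_media, window_series=series, drift=drift
    )
    if regions:
        result.layer_fits = [
            estimate_layer(kymo_media, reg, config, factor=layer_factor) for reg in regions
        ]
        sml = [f for f in result.layer_fits if not f.low_confidence]
        if len(sml) >= 3:
            result.radial_r, result.radial_p = radial_trend(sml)
    return result


def recover_scenario(
    scenario: SyntheticScenario,
    factor: int = 5,
    config: FitConfig | None = None,
    correct_drift: bool = False,
    regions: list[LayerRegion] | None = None,
    layer_factor: int = 1,
) -> PipelineResult:
    """Simulate a scenario, render the stack and run the full pipeline on it."""
    stack, _ = make_stack(scenario)
    n_px = stack.frame_shape[0]
    return run_pipeline(
        stack,
        r_iel_pixel=0,
        r_eel_pixel=n_px,
        factor=factor,
        correct_drift=correct_drift or scenario.drift is not None,
        config=config,
        regions=regions,
        layer_factor=layer_factor,
    )
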