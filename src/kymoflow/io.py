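"""Reading and writing the on-disk formats.

Stacks travel as multi-page TIFF with a YAML sidecar carrying the physical
metadata (pixel sizes, frame clock, arc geometry, media bounds, layer
windows); tabular outputs are CSV via pandas.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from .containers import DriftTrace, FlowFit, ImageStack, Kymograph, LayerRegion
from .layers import make_region

__all__ = [
    "read_stack",
    "write_stack",
    "read_annotations",
    "write_drift_csv",
    "write_flowfit_csv",
    "write_kymograph_csv",
    "regions_from_annotations",
]


def read_stack(tiff_path: str | Path, annotations: dict[str, Any]) -> ImageStack:
    """Load a multi-page (or 3-D) TIFF as an ImageStack.

    The frame clock comes from ``timestamps`` (explicit list, seconds) or
    ``frame_interval`` in the annotations.
    """
    frames = np.asarray(tifffile.imread(str(tiff_path)), dtype=float)
    if frames.ndim == 2:
        frames = frames[None, :, :]
    if "timestamps" in annotations:
        timestamps = np.asarray(annotations["timestamps"], dtype=float)
    elif "frame_interval" in annotations:
        timestamps = np.arange(frames.shape[0]) * float(annotations["frame_interval"])
    else:
        raise ValueError("annotations must provide 'timestamps' or 'frame_interval'")
    return ImageStack(
        frames=frames,
        timestamps=timestamps,
        pixel_size_r=float(annotations.get("pixel_size_r", 0.41)),
        pixel_size_theta=float(annotations.get("pixel_size_theta", 0.41)),
        meta={k: v for k, v in annotations.items() if k not in ("timestamps",)},
    )


def write_stack(stack: ImageStack, tiff_path: str | Path) -> Path:
    tiff_path = Path(tiff_path)
    tifffile.imwrite(str(tiff_path), stack.frames.astype(np.float32))
    return tiff_path


def read_annotations(yaml_path: str | Path) -> dict[str, Any]:
    with open(yaml_path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"annotation file {yaml_path} must hold a mapping")
    return data


def regions_from_annotations(
    annotations: dict[str, Any], n_media_rows: int, dr: float
) -> list[LayerRegion]:
    """Build layer windows from an annotations ``layers`` list.

    Each entry: ``{label: SML1, r_lo: 12, r_hi: 20}`` with rows relative to
    the IEL in the native-resolution media kymograph.
    """
    regions = []
    for entry in annotations.get("layers", []):
        regions.append(
            make_region(
                label=str(entry["label"]),
                r_lo=int(entry["r_lo"]),
                r_hi=int(entry["r_hi"]),
                n_media_rows=n_media_rows,
                dr=dr,
            )
        )
    return regions


def write_drift_csv(trace: DriftTrace, path: str | Path) -> Path:
    path = Path(path)
    trace.to_frame().to_csv(path, index=False)
    return path


def write_flowfit_csv(fits: list[FlowFit], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([f.to_dict() for f in fits]).to_csv(path, index=False)
    return path


def write_kymograph_csv(kymo: Kymograph, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(kymo.values, index=kymo.r, columns=kymo.t)
    df.index.name = "r_um"
    df.columns.name = "t_s"
    df.to_csv(path)
    return path
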