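"""QC figures: window-detection trace, kymograph image, gradient scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .containers import FlowFit, GradientSampleSet, Kymograph

__all__ = ["plot_intensity_series", "plot_kymograph", "plot_gradient_scatter"]


def plot_intensity_series(series: np.ndarray, window, path: str | Path) -> Path:
    """Mean wall intensity vs time with the detected analysis window marked."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    t = np.arange(len(series))
    ax.plot(t, series, ".", ms=3, color="0.3", label="mean intensity")
    ax.axvline(window.t_start, color="tab:green", lw=1, label=r"$t_{start}$")
    ax.axvline(window.t_end, color="tab:red", lw=1, label=r"$t_{end}$")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("intensity (a.u.)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_kymograph(kymo: Kymograph, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 3.5))
    im = ax.imshow(
        kymo.values,
        aspect="auto",
        origin="lower",
        extent=(0, kymo.n_t * kymo.dt, 0, kymo.n_r * kymo.dr),
        cmap="inferno",
    )
    ax.set_xlabel("t from start (s)")
    ax.set_ylabel("r from IEL (µm)")
    fig.colorbar(im, ax=ax, label="normalized intensity" if kymo.normalized else "intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_gradient_scatter(samples: GradientSampleSet, fit: FlowFit, path: str | Path) -> Path:
    """The (b', a') scatter with the fitted transport line."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    keep = samples.retained
    dropped = samples.usable & ~samples.inlier
    ax.plot(samples.b_prime[keep], samples.a_prime[keep], ".", ms=2, color="0.2",
            label=f"inliers (n={fit.n_plot})")
    if dropped.any():
        ax.plot(samples.b_prime[dropped], samples.a_prime[dropped], "x", ms=3,
                color="tab:red", label="excluded")
    xs = np.array(ax.get_xlim())
    ax.plot(xs, fit.v * xs + fit.k, "-", color="tab:blue", lw=1,
            label=f"a' = {fit.v:.2f} b' + {fit.k:.2f}")
    ax.set_xlabel("b' (µm)")
    ax.set_ylabel("a' (µm²/s)")
    ax.set_title(f"R = {fit.r_value:.2f}, p = {fit.p_value:.2g}", fontsize=9)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
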