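"""Advection–diffusion parameter estimation from a normalized kymograph.

The transport balance ∂φ/∂t + v ∂φ/∂r − k ∂²φ/∂r² = 0 is discretized per
pixel with a forward time difference ``a``, forward radial difference ``b``
and central second radial difference ``c``.  Dividing through by the curvature
turns the balance into the straight line

    a' = v·b' + k,        a' = a/c,   b' = −b/c,

so one least-squares line through the per-pixel (b', a') scatter yields the
flow velocity (slope, µm/s) and the diffusion coefficient (intercept, µm²/s).
Pixels with negligible curvature, pixels outside the diagonal analysis band of
the kymograph, and robust (Stahel–Donoho) outliers are excluded first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator, OutlierMixin, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .containers import FlowFit, GradientSampleSet, Kymograph

__all__ = [
    "FitConfig",
    "finite_differences",
    "band_mask",
    "stahel_donoho_outlyingness",
    "StahelDonohoOutlierDetector",
    "remove_outliers",
    "fit_line",
    "estimate",
    "AdvectionDiffusionRegressor",
    "KymographVelocimeter",
]

# Below this curvature magnitude (1/µm², on normalized intensity) the ratios
# a/c and b/c blow up; such pixels are dropped before the robust step.
DEFAULT_C_MIN = 1e-4
DEFAULT_SD_QUANTILE = 0.999
MIN_SAMPLES_FOR_REJECTION = 5


@dataclass
class FitConfig:
    """Tunable knobs of the gradient-regression stage."""

    c_min: float = DEFAULT_C_MIN
    sd_quantile: float = DEFAULT_SD_QUANTILE
    n_exact_max: int = 500
    n_directions: int = 1000
    deming: bool = False
    random_state: int = 0


def finite_differences(kymo: Kymograph, c_min: float = DEFAULT_C_MIN) -> GradientSampleSet:
    """Per-pixel forward/central differences of the normalized kymograph.

    Boundary pixels (last time column, first and last radial rows) are
    excluded; so are pixels touching an invalid row or masked value.  ``r`` and
    ``t`` are physical coordinates (µm from the IEL, s from t_start).
    """
    if not kymo.normalized:
        raise ValueError("finite differences require a normalized kymograph")
    if kymo.n_r < 3 or kymo.n_t < 2:
        raise ValueError(f"kymograph too small ({kymo.n_r}×{kymo.n_t}); need at least 3×2")
    phi = kymo.values
    dr, dt = kymo.dr, kymo.dt

    a = (phi[1:-1, 1:] - phi[1:-1, :-1]) / dt
    b = (phi[2:, :-1] - phi[1:-1, :-1]) / dr
    c = (phi[2:, :-1] - 2.0 * phi[1:-1, :-1] + phi[:-2, :-1]) / dr**2

    ok_rows = kymo.row_valid[:-2] & kymo.row_valid[1:-1] & kymo.row_valid[2:]
    ok_mask = (
        kymo.mask[1:-1, 1:]
        & kymo.mask[1:-1, :-1]
        & kymo.mask[2:, :-1]
        & kymo.mask[:-2, :-1]
    )
    valid = ok_rows[:, None] & ok_mask

    r_idx, t_idx = np.meshgrid(np.arange(1, kymo.n_r - 1), np.arange(kymo.n_t - 1), indexing="ij")
    finite = valid & (np.abs(c) >= c_min)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_prime = np.where(finite, a / np.where(finite, c, 1.0), np.nan)
        b_prime = np.where(finite, -b / np.where(finite, c, 1.0), np.nan)

    flat = lambda x: np.asarray(x).ravel()
    return GradientSampleSet(
        r=flat(r_idx) * dr,
        t=flat(t_idx) * dt,
        a=flat(a),
        b=flat(b),
        c=flat(c),
        a_prime=flat(a_prime),
        b_prime=flat(b_prime),
        finite=flat(finite),
        in_band=np.ones(r_idx.size, dtype=bool),
        inlier=np.ones(r_idx.size, dtype=bool),
    )


def band_mask(r: np.ndarray, t: np.ndarray, r_eel: float, t_end: float) -> np.ndarray:
    """Diagonal analysis band of the kymograph.

    Keeps (r, t) with (2·r_EEL/t_end)·t − r_EEL ≤ r ≤ (2·r_EEL/t_end)·t for
    0 ≤ r ≤ r_EEL, t measured from t_start.  The band tracks the advancing dye
    front and discards the flat corners where intensity changes are too small
    for stable differentiation.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    r = np.asarray(r, dtype=float)
    t = np.asarray(t, dtype=float)
    slope = 2.0 * r_eel / t_end
    tol = 1e-9 * max(r_eel, 1.0)
    lower = slope * t - r_eel
    upper = slope * t
    return (r >= lower - tol) & (r <= upper + tol) & (r >= -tol) & (r <= r_eel + tol)


def apply_band(samples: GradientSampleSet, r_eel: float, t_end: float) -> GradientSampleSet:
    """Set the ``in_band`` flags of a sample set (returns the same object)."""
    samples.in_band = band_mask(samples.r, samples.t, r_eel, t_end)
    return samples


def _pair_directions(X: np.ndarray) -> np.ndarray:
    """Unit directions spanned by every point pair (exact search space)."""
    n = len(X)
    ii, jj = np.triu_indices(n, k=1)
    d = X[ii] - X[jj]
    norms = np.linalg.norm(d, axis=1)
    d = d[norms > 0]
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def stahel_donoho_outlyingness(
    X: np.ndarray,
    n_exact_max: int = 500,
    n_directions: int = 1000,
    random_state: int | None = 0,
    directions: np.ndarray | None = None,
) -> np.ndarray:
    """Max over projection directions of the robust z-score |x·u − med|/MAD.

    For n ≤ ``n_exact_max`` every point-pair direction is searched (exact for
    the pairwise criterion); otherwise ``n_directions`` seeded random unit
    directions are used.  The MAD is scaled for normal consistency (1.4826).
    A direction along which the MAD vanishes assigns infinite outlyingness to
    any point off the common median, and zero to points on it.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n_samples, n_features)")
    n, p = X.shape
    if directions is None:
        if n <= n_exact_max:
            directions = _pair_directions(X)
        else:
            rng = np.random.default_rng(random_state)
            d = rng.standard_normal((n_directions, p))
            directions = d / np.linalg.norm(d, axis=1, keepdims=True)
    if len(directions) == 0:  # all points identical
        return np.zeros(n)
    return _max_projection_score(X, directions)[0]


def _max_projection_score(
    X: np.ndarray,
    directions: np.ndarray,
    medians: np.ndarray | None = None,
    mads: np.ndarray | None = None,
    chunk: int = 4096,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Running max of |proj − med|/MAD over direction chunks (bounded memory)."""
    n = len(X)
    best = np.zeros(n)
    meds = np.empty(len(directions))
    mds = np.empty(len(directions))
    for lo in range(0, len(directions), chunk):
        d = directions[lo : lo + chunk]
        proj = X @ d.T
        if medians is None:
            med = np.median(proj, axis=0)
            mad = 1.4826 * np.median(np.abs(proj - med), axis=0)
        else:
            med = medians[lo : lo + chunk]
            mad = mads[lo : lo + chunk]
        meds[lo : lo + chunk] = med
        mds[lo : lo + chunk] = mad
        dev = np.abs(proj - med)
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(
                mad > 0,
                dev / np.where(mad > 0, mad, 1.0),
                np.where(dev > 0, np.inf, 0.0),
            )
        np.maximum(best, score.max(axis=1), out=best)
    return best, meds, mds


class StahelDonohoOutlierDetector(OutlierMixin, BaseEstimator):
    """Robust multivariate outlier detector based on projection outlyingness.

    A point's outlyingness is its worst robust z-score over projection
    directions; points whose squared outlyingness exceeds the chi-square
    quantile ``quantile`` (df = n_features) are flagged as outliers.  With
    ``n_exact_max`` at least the sample size, the direction search is exact
    over all point pairs and the detector is fully deterministic; beyond that
    a seeded random direction sample is used.

    Follows the scikit-learn outlier-detector API: ``fit_predict`` returns
    +1 for inliers and −1 for outliers.
    """

    def __init__(
        self,
        quantile: float = DEFAULT_SD_QUANTILE,
        n_exact_max: int = 500,
        n_directions: int = 1000,
        random_state: int | None = 0,
    ):
        self.quantile = quantile
        self.n_exact_max = n_exact_max
        self.n_directions = n_directions
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) < 1:
            raise ValueError("X must be a non-empty 2-D array")
        n, p = X.shape
        if n <= self.n_exact_max:
            self.directions_ = _pair_directions(X)
        else:
            rng = np.random.default_rng(self.random_state)
            d = rng.standard_normal((self.n_directions, p))
            self.directions_ = d / np.linalg.norm(d, axis=1, keepdims=True)
        if len(self.directions_) == 0:
            self.medians_ = np.zeros(0)
            self.mads_ = np.zeros(0)
            self.outlyingness_ = np.zeros(n)
        else:
            self.outlyingness_, self.medians_, self.mads_ = _max_projection_score(
                X, self.directions_
            )
        self.threshold_ = float(np.sqrt(sps.chi2.ppf(self.quantile, df=p)))
        self.n_features_in_ = p
        return self

    def _score(self, X: np.ndarray) -> np.ndarray:
        if len(self.directions_) == 0:
            return np.zeros(len(X))
        return _max_projection_score(X, self.directions_, self.medians_, self.mads_)[0]

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "threshold_")
        return self.threshold_ - self._score(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, 1, -1)


def remove_outliers(
    samples: GradientSampleSet,
    seed: int = 0,
    quantile: float = DEFAULT_SD_QUANTILE,
    n_exact_max: int = 500,
    n_directions: int = 1000,
) -> GradientSampleSet:
    """Flag extreme (b', a') points via Stahel–Donoho outlyingness.

    Only finite, in-band samples participate; with fewer than
    ``MIN_SAMPLES_FOR_REJECTION`` of them the set passes through untouched
    (warning).  Returns the same object with ``inlier`` flags updated.
    """
    usable = samples.usable
    n = int(np.count_nonzero(usable))
    if n < MIN_SAMPLES_FOR_REJECTION:
        warnings.warn(
            f"only {n} usable samples; skipping outlier rejection", stacklevel=2
        )
        samples.inlier = np.ones(len(samples.r), dtype=bool)
        return samples
    X = np.column_stack([samples.b_prime[usable], samples.a_prime[usable]])
    det = StahelDonohoOutlierDetector(
        quantile=quantile,
        n_exact_max=n_exact_max,
        n_directions=n_directions,
        random_state=seed,
    )
    labels = det.fit_predict(X)
    inlier = np.ones(len(samples.r), dtype=bool)
    inlier[np.nonzero(usable)[0]] = labels == 1
    samples.inlier = inlier
    return samples


def _deming_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    slope = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4.0 * sxy**2)) / (2.0 * sxy)
    return slope, float(np.mean(y) - slope * np.mean(x))


def fit_line(
    samples: GradientSampleSet,
    deming: bool = False,
    label: str = "whole-media",
) -> FlowFit:
    """Least-squares line through the retained (b', a') scatter.

    Slope → velocity v (µm/s), intercept → diffusion coefficient k (µm²/s);
    R and p from the Pearson correlation t-test on the same points.  The
    optional Deming mode (errors in both variables, unit variance ratio) is
    off by default.
    """
    keep = samples.retained
    n = int(np.count_nonzero(keep))
    if n < 3:
        raise ValueError(f"need at least 3 retained samples, have {n}")
    x = samples.b_prime[keep]
    y = samples.a_prime[keep]
    if np.ptp(x) == 0:
        raise ValueError("degenerate scatter: zero variance in b'")
    res = sps.linregress(x, y)
    if deming:
        v, k = _deming_slope(x, y)
    else:
        v, k = float(res.slope), float(res.intercept)
    if k < 0:
        warnings.warn(f"negative diffusion coefficient fitted (k={k:.3g})", stacklevel=2)
    r_value = float(res.rvalue)
    p_value = float(res.pvalue) if np.ptp(y) > 0 else 1.0
    return FlowFit(
        v=v, k=k, r_value=np.clip(r_value, -1.0, 1.0), p_value=p_value,
        n_plot=n, label=label,
    )


def estimate(
    kymo: Kymograph,
    config: FitConfig | None = None,
    label: str = "whole-media",
) -> FlowFit:
    """Full gradient-regression stage on one normalized kymograph."""
    config = config or FitConfig()
    samples = finite_differences(kymo, c_min=config.c_min)
    apply_band(samples, r_eel=kymo.r_eel, t_end=kymo.window.duration)
    if not samples.usable.any():
        raise ValueError("no usable gradient samples (field too flat?)")
    remove_outliers(
        samples,
        seed=config.random_state,
        quantile=config.sd_quantile,
        n_exact_max=config.n_exact_max,
        n_directions=config.n_directions,
    )
    fit = fit_line(samples, deming=config.deming, label=label)
    fit.meta["samples"] = samples
    return fit


class AdvectionDiffusionRegressor(RegressorMixin, BaseEstimator):
    """Linear fit of a' on b' with optional robust outlier rejection.

    scikit-learn regressor over the gradient scatter: ``X`` is the (n, 1)
    column of b' values (µm), ``y`` the a' values (µm²/s).  Fitted attributes:
    ``velocity_`` (slope, = ``coef_[0]``), ``diffusion_`` (intercept),
    ``r_value_``, ``p_value_`` and ``n_plot_`` over the inliers, plus
    ``inlier_mask_``.
    """

    def __init__(
        self,
        reject_outliers: bool = True,
        quantile: float = DEFAULT_SD_QUANTILE,
        n_exact_max: int = 500,
        n_directions: int = 1000,
        deming: bool = False,
        random_state: int | None = 0,
    ):
        self.reject_outliers = reject_outliers
        self.quantile = quantile
        self.n_exact_max = n_exact_max
        self.n_directions = n_directions
        self.deming = deming
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != 1:
            raise ValueError("expects a single feature (the b' column)")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        x = X[:, 0]
        inlier = np.ones(len(x), dtype=bool)
        if self.reject_outliers and len(x) >= MIN_SAMPLES_FOR_REJECTION:
            det = StahelDonohoOutlierDetector(
                quantile=self.quantile,
                n_exact_max=self.n_exact_max,
                n_directions=self.n_directions,
                random_state=self.random_state,
            )
            inlier = det.fit_predict(np.column_stack([x, y])) == 1
        xi, yi = x[inlier], y[inlier]
        if len(xi) < 3:
            raise ValueError("fewer than 3 inlier samples")
        if np.ptp(xi) == 0:
            raise ValueError("degenerate scatter: zero variance in b'")
        res = sps.linregress(xi, yi)
        if self.deming:
            slope, intercept = _deming_slope(xi, yi)
        else:
            slope, intercept = float(res.slope), float(res.intercept)
        self.coef_ = np.array([slope])
        self.intercept_ = intercept
        self.velocity_ = slope
        self.diffusion_ = intercept
        self.r_value_ = float(res.rvalue)
        self.p_value_ = float(res.pvalue)
        self.n_plot_ = int(len(xi))
        self.inlier_mask_ = inlier
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X[:, 0] * self.coef_[0] + self.intercept_


class KymographVelocimeter(BaseEstimator):
    """End-of-pipeline estimator: normalized kymograph in, (v, k) out.

    ``fit`` runs finite differencing, band selection, Stahel–Donoho rejection
    and the least-squares line; fitted attributes are ``velocity_`` (µm/s),
    ``diffusion_`` (µm²/s), ``r_value_``, ``p_value_``, ``n_plot_`` and the
    full ``samples_`` set for QC plots.
    """

    def __init__(
        self,
        c_min: float = DEFAULT_C_MIN,
        sd_quantile: float = DEFAULT_SD_QUANTILE,
        n_exact_max: int = 500,
        n_directions: int = 1000,
        deming: bool = False,
        random_state: int = 0,
    ):
        self.c_min = c_min
        self.sd_quantile = sd_quantile
        self.n_exact_max = n_exact_max
        self.n_directions = n_directions
        self.deming = deming
        self.random_state = random_state

    def _config(self) -> FitConfig:
        return FitConfig(
            c_min=self.c_min,
            sd_quantile=self.sd_quantile,
            n_exact_max=self.n_exact_max,
            n_directions=self.n_directions,
            deming=self.deming,
            random_state=self.random_state,
        )

    def fit(self, X: Kymograph, y=None):
        if not isinstance(X, Kymograph):
            raise TypeError("KymographVelocimeter.fit expects a Kymograph")
        flow = estimate(X, self._config())
        self.flow_fit_ = flow
        self.samples_ = flow.meta["samples"]
        self.velocity_ = flow.v
        self.diffusion_ = flow.k
        self.r_value_ = flow.r_value
        self.p_value_ = flow.p_value
        self.n_plot_ = flow.n_plot
        return self
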