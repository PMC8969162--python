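"""Statistical tests and closed-form sanity checks.

Pearson correlations are tested with the Student's t transform; all-pairs
group comparisons use the Steel–Dwass procedure (the nonparametric analogue
of Tukey's HSD), with midrank tie handling and either the asymptotic
studentized-range reference distribution or, for small samples, the exact
joint permutation distribution of the maximum pairwise statistic.

The remaining helpers are the small analytic estimates used to sanity-check a
velocity measurement: the continuity-of-flux bound across a curved wall, the
finite scan-speed error, the porosity (superficial → interstitial) correction
and the Peclet number.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, prod

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "PairwiseComparison",
    "pearson_test",
    "steel_dwass",
    "curvature_velocity_drop",
    "scan_error_fraction",
    "porosity_correction",
    "peclet_number",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    t_stat: float
    df: int
    p: float

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("df must be positive")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p outside [0, 1]")


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    statistic: float
    p: float

    def involves(self, label: str) -> bool:
        return label in self.pair


def pearson_test(x, y) -> CorrelationResult:
    """Pearson R with the two-sided Student's t-test, df = n − 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2
    if abs(r) >= 1.0:
        return CorrelationResult(r=r, t_stat=np.inf if r > 0 else -np.inf, df=df, p=0.0)
    t = r * np.sqrt(df) / np.sqrt(1.0 - r**2)
    p = float(2.0 * sps.t.sf(abs(t), df))
    return CorrelationResult(r=r, t_stat=float(t), df=df, p=min(p, 1.0))


def _pair_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized rank-sum of ``x`` within the pooled pair, midrank ties."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    m, n_ = len(x), len(y)
    ns = m + n_
    w = ranks[:m].sum()
    expect = m * (ns + 1) / 2.0
    var = m * n_ / (ns * (ns - 1.0)) * float(((ranks - (ns + 1) / 2.0) ** 2).sum())
    if var <= 0:
        return 0.0
    return float((w - expect) / np.sqrt(var))


def _comparison_matrix(values: np.ndarray) -> np.ndarray:
    diff_lt = values[None, :] < values[:, None]
    diff_eq = values[None, :] == values[:, None]
    c = diff_lt.astype(float) + 0.5 * diff_eq.astype(float)
    np.fill_diagonal(c, 0.0)
    return c


def _partition_memberships(sizes: list[int]):
    """Yield group-membership index tuples for every partition of range(N)."""
    indices = tuple(range(sum(sizes)))

    def rec(avail: tuple[int, ...], sizes_left: list[int]):
        if len(sizes_left) == 1:
            yield (avail,)
            return
        for combo in combinations(avail, sizes_left[0]):
            chosen = set(combo)
            rest = tuple(i for i in avail if i not in chosen)
            for tail in rec(rest, sizes_left[1:]):
                yield (combo,) + tail

    yield from rec(indices, sizes)


def _exact_steel_dwass_p(groups: list[np.ndarray], observed: dict[tuple[int, int], float],
                         chunk: int = 65536) -> dict[tuple[int, int], float]:
    """Joint-permutation null of the max pairwise statistic, fully enumerated."""
    sizes = [len(g) for g in groups]
    n_total = sum(sizes)
    total = prod(comb(sum(sizes[i:]), sizes[i]) for i in range(len(sizes) - 1))
    if total > 2_000_000:
        raise ValueError(
            f"exact Steel–Dwass enumeration infeasible: {total} partitions"
        )
    values = np.concatenate(groups)
    cmat = _comparison_matrix(values)
    pairs = list(combinations(range(len(groups)), 2))

    max_stat = np.empty(total)
    row = 0
    filled = 0
    group_of = np.empty(n_total, dtype=int)

    def flush(mbuf: np.ndarray, count: int, start: int) -> None:
        # mbuf encodes group labels 0..k-1 per item
        chunk_max = np.full(count, -np.inf)
        for gi, gj in pairs:
            mg = (mbuf[:count] == gi).astype(np.float64)
            mh = (mbuf[:count] == gj).astype(np.float64)
            ms = mg + mh
            g = ms @ cmat.T  # (count, N): Σ_j C[i,j]·mS[j]
            ranks = 1.0 + g
            w = (mg * ranks).sum(axis=1)
            m_, n_ = sizes[gi], sizes[gj]
            ns = m_ + n_
            expect = m_ * (ns + 1) / 2.0
            sumsq = (ms * (ranks - (ns + 1) / 2.0) ** 2).sum(axis=1)
            var = m_ * n_ / (ns * (ns - 1.0)) * sumsq
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(var > 0, (w - expect) / np.sqrt(np.maximum(var, 1e-300)), 0.0)
            chunk_max = np.maximum(chunk_max, np.abs(t))
        max_stat[start : start + count] = chunk_max

    mbuf = np.zeros((chunk, n_total), dtype=np.int8)
    for membership in _partition_memberships(sizes):
        for gi, idxs in enumerate(membership):
            group_of[list(idxs)] = gi
        mbuf[filled] = group_of
        filled += 1
        if filled == chunk:
            flush(mbuf, filled, row)
            row += filled
            filled = 0
    if filled:
        flush(mbuf, filled, row)
        row += filled

    return {
        pair: float(np.mean(max_stat >= abs(obs) - 1e-9))
        for pair, obs in observed.items()
    }


def steel_dwass(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
    method: str = "asymptotic",
) -> list[PairwiseComparison]:
    """All-pairs rank comparison with family-wise adjustment.

    For each pair of groups the Wilcoxon rank-sum statistic is standardized on
    the pair's pooled midranks; the asymptotic p refers √2·|t| to the
    studentized-range distribution with as many groups as compared
    (``method='asymptotic'``), while ``method='exact'`` enumerates the joint
    permutation distribution of the maximum pairwise statistic (small samples
    only).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(groups):
        if len(g) == 0:
            raise ValueError(f"group {i} has zero observations")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    if len(labels) != len(groups):
        raise ValueError("one label per group required")
    k = len(groups)
    pairs = list(combinations(range(k), 2))
    observed = {(i, j): _pair_statistic(groups[i], groups[j]) for i, j in pairs}

    if method == "asymptotic":
        # continuity-corrected: the rank-sum moves in steps, so pull |W - E|
        # back by half a step before standardizing
        pvals = {}
        for (i, j), t in observed.items():
            m, n_ = len(groups[i]), len(groups[j])
            ns = m + n_
            pooled = np.concatenate([groups[i], groups[j]])
            ranks = sps.rankdata(pooled)
            var = m * n_ / (ns * (ns - 1.0)) * float(((ranks - (ns + 1) / 2.0) ** 2).sum())
            if var <= 0:
                pvals[(i, j)] = 1.0
                continue
            t_cc = max(abs(t) * np.sqrt(var) - 0.5, 0.0) / np.sqrt(var)
            pvals[(i, j)] = float(sps.studentized_range.sf(np.sqrt(2.0) * t_cc, k, np.inf))
    elif method == "exact":
        pvals = _exact_steel_dwass_p(groups, observed)
    else:
        raise ValueError(f"unknown method {method!r}")
    return [
        PairwiseComparison(
            pair=(labels[i], labels[j]),
            statistic=observed[(i, j)],
            p=min(1.0, pvals[(i, j)]),
        )
        for i, j in pairs
    ]


def curvature_velocity_drop(r_inner: float, r_outer: float) -> float:
    """Continuity-of-flux bound on the radial velocity decrease, 1 − r_in/r_out.

    Across a cylindrical wall the same volume flux crosses a larger surface on
    the outer side, so the velocity can drop at most by this fraction on
    geometric grounds alone.
    """
    if not 0 < r_inner <= r_outer:
        raise ValueError("need 0 < r_inner <= r_outer")
    return 1.0 - r_inner / r_outer


def scan_error_fraction(v: float, scan_speed: float) -> float:
    """Relative velocity error from the finite radial scan speed, v / v_scan."""
    if scan_speed <= 0:
        raise ValueError("scan_speed must be positive")
    return v / scan_speed


def porosity_correction(v_superficial: float, flow_area_fraction: float) -> float:
    """True interstitial velocity from the superficial one, v / porosity."""
    if not 0.0 < flow_area_fraction <= 1.0:
        raise ValueError("flow_area_fraction must lie in (0, 1]")
    return v_superficial / flow_area_fraction


def peclet_number(v: float, length: float, k: float) -> float:
    """Advective over diffusive transport, v·L/k; ≫1 means flow-dominated."""
    if k <= 0:
        raise ValueError("k must be positive (advection-only transport has no Peclet number)")
    if length <= 0:
        raise ValueError("length must be positive")
    return v * length / k
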