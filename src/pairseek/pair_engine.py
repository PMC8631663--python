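"""Dichotomized pairwise taxon variables and out-of-sample threshold search.

For an ordered taxon pair (i, j) and a fold-threshold c > 0, the pair
indicator for sample k is

    Z_k = 1(X_ik <= c * X_jk),

i.e. "taxon i is at most c-fold above taxon j within sample k". Because the
comparison is a within-sample ratio, Z is unchanged by any per-sample
rescaling of the counts — no normalization of sequencing depth is needed.
Samples where both counts are zero carry no ratio information and are
randomized to 0 or 1 with probability one half.

The threshold c is chosen on held-out data by minimizing a weighted
Gini-style impurity of the case/control split induced by Z, scanned over a
grid spanning the 20th-80th percentiles of the observed ratios X_i/X_j.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = [
    "ThresholdGrid",
    "dichotomize",
    "pair_ratios",
    "build_threshold_grid",
    "impurity",
    "select_threshold",
    "enumerate_pairs",
    "orient_pair",
]


@dataclass
class ThresholdGrid:
    """Sorted candidate fold-thresholds c, all finite and positive."""

    values: np.ndarray
    lo_quantile: float = 0.2
    hi_quantile: float = 0.8
    n_points: int = 50

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("grid must be a non-empty 1-D vector")
        if np.any(~np.isfinite(values)) or np.any(values <= 0):
            raise ValueError("grid values must be finite and > 0")
        if np.any(np.diff(values) <= 0):
            raise ValueError("grid values must be strictly increasing")
        self.values = values


def pair_ratios(xi: np.ndarray, xj: np.ndarray) -> np.ndarray:
    """Per-sample ratios xi/xj: inf where xj=0<xi, NaN where both are zero.

    All downstream decisions compare these ratios to c. Working on the ratio
    scale (rather than evaluating ``xi <= c*xj`` directly) makes the pipeline
    bit-exactly invariant to per-sample integer rescaling of the counts.
    """
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape:
        raise ValueError("xi and xj must have the same length")
    if np.any(xi < 0) or np.any(xj < 0):
        raise ValueError("counts must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        return xi / xj


def dichotomize(xi, xj, c: float, rng=None, u: np.ndarray | None = None) -> np.ndarray:
    """Binary pair indicator Z = 1(xi <= c * xj), zero/zero samples randomized.

    Parameters
    ----------
    c
        Positive fold-threshold.
    rng
        `numpy.random.Generator` used for the zero/zero randomization.
    u
        Optional pre-drawn uniforms (full sample length); overrides ``rng``.
        Passing the same ``u`` across several calls keeps the zero/zero
        randomization fixed while c varies.
    """
    if not c > 0:
        raise ValueError("threshold c must be > 0")
    r = pair_ratios(xi, xj)
    z = (r <= c)  # NaN and inf compare False
    both_zero = np.isnan(r)
    if both_zero.any():
        if u is None:
            if rng is None:
                raise ValueError("zero/zero samples present: rng or u required")
            u = rng.random(r.shape[0])
        z = z | (both_zero & (np.asarray(u) < 0.5))
    return z.astype(np.int8)


def build_threshold_grid(
    xi,
    xj,
    lo: float = 0.2,
    hi: float = 0.8,
    n_points: int = 50,
) -> ThresholdGrid:
    """Equally spaced candidate thresholds between ratio quantiles.

    Quantiles use linear interpolation between order statistics. Ratios with
    xj=0 (infinite) or 0/0 (undefined) are excluded. Degenerate cases fall
    back to a single-value grid: no finite ratio -> {1}; a single distinct
    ratio value v>0 -> {v}. Non-positive grid points (possible when many
    ratios are zero) are dropped.
    """
    if not (0 < lo < hi < 1):
        raise ValueError("quantiles must satisfy 0 < lo < hi < 1")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    r = pair_ratios(xi, xj)
    finite = r[np.isfinite(r)]
    if finite.size == 0:
        return ThresholdGrid(np.array([1.0]), lo, hi, n_points)
    qlo, qhi = np.quantile(finite, [lo, hi])
    if qlo == qhi:
        value = qhi if qhi > 0 else 1.0
        return ThresholdGrid(np.array([value]), lo, hi, n_points)
    values = np.unique(np.linspace(qlo, qhi, n_points))
    values = values[values > 0]
    if values.size == 0:
        values = np.array([1.0])
    return ThresholdGrid(values, lo, hi, n_points)


def impurity(z, y) -> float:
    """Weighted two-branch Gini impurity of the case split induced by z.

    With gamma = mean(z), p1 = case fraction where z=1 and p2 = case fraction
    where z=0, returns gamma*p1*(1-p1) + (1-gamma)*p2*(1-p2). An empty branch
    contributes 0. Bounded in [0, 0.25]; 0 iff both branches are class-pure.
    """
    z = np.asarray(z)
    y = np.asarray(y)
    if z.shape != y.shape:
        raise ValueError("z and y must have the same length")
    n = z.shape[0]
    if n == 0:
        raise ValueError("empty vectors")
    n1 = int(z.sum())
    n0 = n - n1
    cases1 = float(y[z == 1].sum())
    cases0 = float(y.sum()) - cases1
    out = 0.0
    if n1:
        p1 = cases1 / n1
        out += (n1 / n) * p1 * (1.0 - p1)
    if n0:
        p2 = cases0 / n0
        out += (n0 / n) * p2 * (1.0 - p2)
    return out


def impurity_profile(
    r: np.ndarray, y: np.ndarray, grid: np.ndarray, u: np.ndarray
) -> np.ndarray:
    """Impurity at every grid threshold, sharing one zero/zero randomization.

    ``r`` are precomputed pair ratios, ``u`` uniforms of the same length.
    Vectorized over the grid; used by both the public threshold search and
    the stability-selection engine.
    """
    z = r[None, :] <= np.asarray(grid, dtype=float)[:, None]
    both_zero = np.isnan(r)
    if both_zero.any():
        z = z | (both_zero & (u < 0.5))[None, :]
    n = r.shape[0]
    y = np.asarray(y, dtype=float)
    total_cases = y.sum()
    n1 = z.sum(axis=1)
    cases1 = z @ y
    n0 = n - n1
    cases0 = total_cases - cases1
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(n1 > 0, cases1 / np.maximum(n1, 1), 0.0)
        p2 = np.where(n0 > 0, cases0 / np.maximum(n0, 1), 0.0)
    return (n1 / n) * p1 * (1.0 - p1) + (n0 / n) * p2 * (1.0 - p2)


def select_threshold(
    xi,
    xj,
    y,
    grid: ThresholdGrid,
    rng=None,
    u: np.ndarray | None = None,
) -> tuple[float, float]:
    """Grid threshold minimizing the impurity of the induced case split.

    The zero/zero randomization is drawn once and reused at every grid point,
    so thresholds are compared on identical indicator backgrounds. Ties go to
    the smallest c. Returns ``(c_star, impurity_star)``.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    r = pair_ratios(xi, xj)
    if u is None:
        if np.isnan(r).any():
            if rng is None:
                raise ValueError("zero/zero samples present: rng or u required")
            u = rng.random(r.shape[0])
        else:
            u = np.empty(r.shape[0])
    profile = impurity_profile(r, y, grid.values, np.asarray(u))
    best = int(np.argmin(profile))  # first minimum = smallest c (grid sorted)
    return float(grid.values[best]), float(profile[best])


def enumerate_pairs(n_taxa: int) -> list[tuple[int, int]]:
    """All unordered taxon index pairs {i, j}, canonicalized as i < j."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa to form pairs")
    return list(combinations(range(n_taxa), 2))


def orient_pair(pair: tuple[int, int], rng) -> tuple[int, int]:
    """Return (i, j) or (j, i) with probability one half each."""
    i, j = pair
    return (i, j) if rng.random() < 0.5 else (j, i)
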