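"""Stability-selection engine ranking taxon pairs by dominance score.

Each of B iterations (1) splits the samples in half at random, (2) orients
every taxon pair at random, (3) picks each pair's fold-threshold c on the
held-out half by impurity minimization, (4) builds the matrix of all pair
indicators on the analysis half and fits an L1-penalized logistic regression
at a penalty drawn at random from a standard LASSO path grid. The dominance
score of a pair is the fraction of iterations in which its indicator kept a
nonzero coefficient — a resampling-stable measure of how strongly the pair's
dichotomized relationship tracks the outcome. Pairs with scores above a
threshold (typically 0.7-0.9) are flagged as candidate signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from ._rng import combine, name_keys, pair_keys, uniforms
from .io_tables import CountTable, OutcomeVector
from .pair_engine import enumerate_pairs

__all__ = [
    "LassoConfig",
    "lambda_grid",
    "fit_lasso_support",
    "pairseek",
    "rank_and_select",
]

_TAG_ORIENT = np.uint64(0xA11CE)
_TAG_ZERO = np.uint64(0xBEE)


@dataclass
class LassoConfig:
    """Penalty-grid configuration for the random-lambda LASSO fits.

    The grid spans ``grid_size`` points (default 100) from lambda_max — the
    smallest penalty with an all-zero fitted support — down to
    ``min_ratio * lambda_max`` (default 0.001). ``spacing`` is ``"log"``
    (standard LASSO-path practice) or ``"linear"``. The intercept is never
    penalized.
    """

    grid_size: int = 100
    min_ratio: float = 0.001
    spacing: str = "log"
    tol: float = 1e-5

    def __post_init__(self) -> None:
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")
        if not 0 < self.min_ratio < 1:
            raise ValueError("min_ratio must be in (0, 1)")
        if self.spacing not in ("log", "linear"):
            raise ValueError("spacing must be 'log' or 'linear'")


def _lambda_max(design: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty with empty support: max_j |X_j^T (y - ybar)| / n.

    Closed form from the KKT conditions at beta = 0 with the intercept at
    logit(mean(y)); predictors enter unstandardized (they are 0/1 indicators
    on a common scale).
    """
    y = np.asarray(y, dtype=float)
    resid = y - y.mean()
    return float(np.abs(resid @ design).max() / y.shape[0])


def _grid_from_max(lam_max: float, config: LassoConfig) -> np.ndarray:
    lam_min = config.min_ratio * lam_max
    if config.spacing == "log":
        return np.geomspace(lam_max, lam_min, config.grid_size)
    return np.linspace(lam_max, lam_min, config.grid_size)


def lambda_grid(design, y, config: LassoConfig = LassoConfig()) -> np.ndarray:
    """Descending penalty grid from lambda_max to min_ratio * lambda_max."""
    design = np.asarray(design, dtype=float)
    if design.ndim != 2 or design.shape[1] < 1:
        raise ValueError("design must be 2-D with at least one column")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    lam_max = _lambda_max(design, y)
    if lam_max <= 0:
        raise ValueError("all predictors are uncorrelated with the outcome "
                         "(lambda_max = 0); no meaningful penalty grid exists")
    return _grid_from_max(lam_max, config)


def _fit_lasso(design, y, lam, tol, max_iter) -> tuple[float, np.ndarray]:
    """(intercept, coefficients) of the penalized fit; raises on non-convergence."""
    n = design.shape[0]
    model = LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / (n * lam),
        solver="liblinear",
        intercept_scaling=100.0,
        tol=tol,
        max_iter=max_iter,
        random_state=0,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(design, y)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        raise RuntimeError(
            f"L1 logistic fit did not converge at lambda={lam:.6g} "
            f"within {max_iter} iterations"
        )
    return float(model.intercept_[0]), model.coef_[0]


def fit_lasso_support(
    design, y, lam: float, tol: float = 1e-6, max_iter: int = 5000
) -> np.ndarray:
    """Column indices with nonzero coefficient in the L1 logistic fit.

    Minimizes ``-(1/n) * loglik + lam * ||beta||_1`` with a (practically)
    unpenalized intercept, via liblinear with C = 1/(n*lam). Predictors are
    not standardized: every column is a 0/1 indicator on a common scale.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    design = np.asarray(design, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    if lam == 0:
        lam = np.finfo(float).tiny
    if lam >= _lambda_max(design, y):
        # KKT: beta = 0 (intercept at logit(ybar)) is exactly optimal at and
        # above lambda_max; no solver call needed (or wanted: a numerical
        # solver can wobble across this boundary)
        return np.array([], dtype=np.int64)
    _, coef = _fit_lasso(design, y, lam, tol, max_iter)
    return np.flatnonzero(coef)


def _draw_split(rng, y: np.ndarray, max_retries: int = 100):
    """Half-sample split with both classes present in each half."""
    n = y.shape[0]
    half = n // 2
    for _ in range(max_retries):
        perm = rng.permutation(n)
        d, d_star = perm[:half], perm[half:]
        if len(np.unique(y[d])) == 2 and len(np.unique(y[d_star])) == 2:
            return np.sort(d), np.sort(d_star)
    raise RuntimeError(
        f"could not draw a half-sample with both classes in {max_retries} tries"
    )


def _row_quantile(r_sorted: np.ndarray, n_fin: np.ndarray, q: float) -> np.ndarray:
    """Linear-interpolation quantile of the first ``n_fin`` entries per row."""
    pos = q * np.maximum(n_fin - 1, 0)
    lo_i = np.floor(pos).astype(np.int64)
    hi_i = np.minimum(lo_i + 1, np.maximum(n_fin - 1, 0))
    frac = pos - lo_i
    a = np.take_along_axis(r_sorted, lo_i[:, None], 1)[:, 0]
    b = np.take_along_axis(r_sorted, hi_i[:, None], 1)[:, 0]
    with np.errstate(invalid="ignore", over="ignore"):  # all-degenerate rows
        return a + frac * (b - a)


def _pair_grids(r_sorted: np.ndarray, n_fin: np.ndarray,
                lo: float, hi: float, n_points: int) -> tuple:
    """Row-wise threshold grids over the finite-ratio quantile span.

    ``r_sorted`` has each pair's held-out ratios sorted ascending (inf, then
    NaN, at the end); ``n_fin`` counts the finite entries per row. Returns
    ``(grids, valid)`` of shape (n_pairs, n_points); invalid entries
    (non-positive or undefined thresholds) are masked out of the search.
    Degenerate rows (no finite ratio, or no positive span) fall back to the
    constant grid {1}, matching the single-pair construction.
    """
    qlo = _row_quantile(r_sorted, n_fin, lo)
    qhi = _row_quantile(r_sorted, n_fin, hi)
    grids = np.linspace(qlo, qhi, n_points, axis=1)
    grids[n_fin == 0] = 1.0
    flat = (n_fin > 0) & (qlo == qhi) & (qlo <= 0)
    grids[flat] = 1.0
    valid = np.isfinite(grids) & (grids > 0)
    dead = ~valid.any(axis=1)
    grids[dead] = 1.0
    valid[dead] = True
    return grids, valid


def _indicators(ratios: np.ndarray, c: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Pair indicators at per-pair thresholds with zero/zero randomization."""
    z = ratios <= c[:, None]
    both_zero = np.isnan(ratios)
    return z | (both_zero & (u < 0.5))


def pairseek(
    table: CountTable,
    y: OutcomeVector,
    B: int = 500,
    s_thr: float = 0.8,
    lo_quantile: float = 0.2,
    hi_quantile: float = 0.8,
    c_grid_points: int = 50,
    lasso: LassoConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank all taxon pairs by dominance score.

    Parameters
    ----------
    table
        Raw count table (no normalization required or wanted: all pair
        comparisons are within-sample ratios).
    y
        Binary outcome aligned to ``table.sample_ids``.
    B
        Number of stability iterations (score resolution is 1/B).
    s_thr
        Dominance-score threshold flagging candidate pairs.
    lo_quantile, hi_quantile, c_grid_points
        Fold-threshold search grid: ``c_grid_points`` equally spaced values
        between these quantiles of each pair's held-out count ratios.
    lasso
        Penalty-grid configuration (see :class:`LassoConfig`).
    seed
        Master seed; fixes the whole run bit-for-bit. Per-pair and per-sample
        substreams are keyed by taxon/sample names, so reordering columns
        permutes the output without changing any score.

    Returns
    -------
    pandas.DataFrame
        One row per unordered pair: ``pair_i, pair_j, dominance_score,
        n_selected, B, median_c, rank, selected`` sorted by rank. ``median_c``
        is the median fold-threshold over the iterations where the pair was
        selected (NaN if never selected).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0 < s_thr <= 1:
        raise ValueError("s_thr must be in (0, 1]")
    if table.n_samples < 10:
        raise ValueError("need at least 10 samples")
    if len(y) != table.n_samples:
        raise ValueError("outcome length does not match the table")
    yv = np.asarray(y.values, dtype=np.int8)
    if len(np.unique(yv)) < 2:
        raise ValueError("outcome must contain both classes")
    lasso = lasso or LassoConfig()
    seed = int(seed)
    if not 0 <= seed < 2**63:
        raise ValueError("seed must be a non-negative 63-bit integer")

    X = table.counts.astype(np.float64).T  # taxa x samples
    n = table.n_samples
    p = table.n_taxa
    pairs = np.asarray(enumerate_pairs(p))
    n_pairs = pairs.shape[0]

    taxon_key = name_keys(table.taxon_ids)
    sample_key = name_keys(table.sample_ids)
    pkey = pair_keys(taxon_key[pairs[:, 0]], taxon_key[pairs[:, 1]])
    # canonical endpoints ordered by taxon key, so orientation draws are
    # invariant to the column order of the input table
    swap = taxon_key[pairs[:, 1]] < taxon_key[pairs[:, 0]]
    first = np.where(swap, pairs[:, 1], pairs[:, 0])
    second = np.where(swap, pairs[:, 0], pairs[:, 1])

    master = np.random.default_rng(seed)
    seed_key = np.uint64(seed)
    selected = np.zeros((B, n_pairs), dtype=bool)
    c_chosen = np.empty((B, n_pairs))
    y_float = yv.astype(np.float64)

    for b in range(B):
        d, d_star = _draw_split(master, yv)
        iter_key = combine(seed_key, np.uint64(b))
        orient_flip = uniforms(combine(iter_key, pkey, _TAG_ORIENT)) < 0.5
        a_idx = np.where(orient_flip, second, first)  # Z = 1(X_a <= c * X_b)
        b_idx = np.where(orient_flip, first, second)
        u_all = uniforms(
            combine(iter_key, pkey[:, None], sample_key[None, :], _TAG_ZERO)
        )

        with np.errstate(divide="ignore", invalid="ignore"):
            r_star = X[a_idx][:, d_star] / X[b_idx][:, d_star]
        # sorted ratios turn the impurity scan into prefix sums: for finite c,
        # #(r <= c) and the case count among them come from one binary search
        order = np.argsort(r_star, axis=1)  # inf then NaN sort last
        r_sorted = np.take_along_axis(r_star, order, axis=1)
        n_fin = np.isfinite(r_star).sum(axis=1)
        grids, valid = _pair_grids(
            r_sorted, n_fin, lo_quantile, hi_quantile, c_grid_points
        )

        y_sub = y_float[d_star]
        n_sub = d_star.shape[0]
        cum_cases = np.concatenate(
            [np.zeros((n_pairs, 1)), np.cumsum(y_sub[order], axis=1)], axis=1
        )
        n1 = np.empty((n_pairs, c_grid_points), dtype=np.int64)
        for k in range(n_pairs):
            n1[k] = np.searchsorted(r_sorted[k], grids[k], side="right")
        cases1 = np.take_along_axis(cum_cases, n1, axis=1)
        # zero/zero samples: one Bernoulli(0.5) draw per (pair, sample) per
        # iteration, shared across all thresholds in the scan
        both_zero = np.isnan(r_star)
        if both_zero.any():
            to_one = both_zero & (u_all[:, d_star] < 0.5)
            n1 = n1 + to_one.sum(axis=1)[:, None]
            cases1 = cases1 + (to_one @ y_sub)[:, None]
        n0 = n_sub - n1
        cases0 = y_sub.sum() - cases1
        with np.errstate(invalid="ignore"):
            p1 = np.where(n1 > 0, cases1 / np.maximum(n1, 1), 0.0)
            p2 = np.where(n0 > 0, cases0 / np.maximum(n0, 1), 0.0)
        imp = (n1 / n_sub) * p1 * (1 - p1) + (n0 / n_sub) * p2 * (1 - p2)
        imp[~valid] = np.inf
        best = np.argmin(imp, axis=1)  # first minimum -> smallest c
        c_star = grids[np.arange(n_pairs), best]
        c_chosen[b] = c_star

        with np.errstate(divide="ignore", invalid="ignore"):
            r_d = X[a_idx][:, d] / X[b_idx][:, d]
        design = _indicators(r_d, c_star, u_all[:, d]).T.astype(np.float64)
        y_d = yv[d]
        lam_max = _lambda_max(design, y_d)
        if lam_max <= 0:
            continue  # nothing can enter the model this iteration
        grid = _grid_from_max(lam_max, lasso)
        lam = float(grid[master.integers(lasso.grid_size)])
        support = fit_lasso_support(design, y_d, lam, tol=lasso.tol)
        selected[b, support] = True

    scores = selected.mean(axis=0)
    n_selected = selected.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN medians
        median_c = np.nanmedian(np.where(selected, c_chosen, np.nan), axis=0)
    ranks = rankdata(-scores, method="min").astype(int)

    taxa = np.asarray(table.taxon_ids)
    out = pd.DataFrame(
        {
            "pair_i": taxa[pairs[:, 0]],
            "pair_j": taxa[pairs[:, 1]],
            "i_index": pairs[:, 0],
            "j_index": pairs[:, 1],
            "dominance_score": scores,
            "n_selected": n_selected,
            "B": B,
            "median_c": median_c,
            "rank": ranks,
            "selected": scores >= s_thr,
        }
    )
    out = out.sort_values(
        ["rank", "i_index", "j_index"], kind="mergesort"
    ).reset_index(drop=True)
    return out


def rank_and_select(dominance: pd.DataFrame, s_thr: float) -> pd.DataFrame:
    """Pairs with dominance score >= ``s_thr``, best first.

    Raising ``s_thr`` never adds a pair (selection is monotone).
    """
    if not 0 < s_thr <= 1:
        raise ValueError("s_thr must be in (0, 1]")
    keep = dominance[dominance["dominance_score"] >= s_thr]
    return keep.sort_values(
        ["rank", "i_index", "j_index"], kind="mergesort"
    ).reset_index(drop=True)
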