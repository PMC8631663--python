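"""Single-pair comparator screens with FDR correction.

The comparator to the stability-selection ranking: each taxon pair is
dichotomized once, outcome-blind, at the no-intercept least-squares line of
taxon i on taxon j (W = 1(X_i > d_hat * X_j)), then a separate logistic
regression of the outcome on W is fitted per pair, optionally adjusting for
the two taxa's main effects on the relative-abundance (RA) or centered
log-ratio (CLR) scale. Benjamini-Hochberg correction runs across all pairs.

A standard multiplicative-interaction screen (y ~ x_i + x_j + x_i*x_j on the
chosen scale) is included, along with a diagnostic quantifying the
correlation that pair markers sharing a taxon induce among themselves.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .io_tables import CountTable, OutcomeVector, clr_transform, relative_abundance
from .pair_engine import enumerate_pairs

__all__ = [
    "fit_origin_slope",
    "single_pair_screen",
    "multiplicative_interaction_screen",
    "bh_fdr",
    "overlap_logodds_diagnostic",
]

ADJUST_MODES = ("none", "ra", "clr")


def fit_origin_slope(xi, xj) -> float:
    """Least-squares slope of xi on xj through the origin: sum(xi*xj)/sum(xj^2)."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape:
        raise ValueError("xi and xj must have the same length")
    denom = float(xj @ xj)
    if denom == 0.0:
        raise ValueError("slope undefined: xj is identically zero")
    return float(xi @ xj) / denom


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN entries stay NaN.

    Missing p-values (degenerate fits) are excluded from the correction
    denominator rather than imputed.
    """
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    if ok.any() and (p[ok].min() < 0 or p[ok].max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _wald_p(y: np.ndarray, design: np.ndarray, col: int) -> tuple[float, bool]:
    """Wald p-value of one column of a logistic fit; (NaN, True) if degenerate."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200, warn_convergence=False)
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
            return np.nan, True
    if not res.mle_retvals.get("converged", False):
        return np.nan, True
    if not np.all(np.isfinite(res.bse)) or np.abs(res.params).max() > 1e3:
        return np.nan, True  # quasi-separation: Wald statistic meaningless
    return float(res.pvalues[col]), False


def _adjustment_matrix(table: CountTable, adjust: str, pseudocount: float):
    if adjust == "none":
        return None
    if adjust == "ra":
        return relative_abundance(table)
    if adjust == "clr":
        return clr_transform(table, pseudocount)
    raise ValueError(f"adjust must be one of {ADJUST_MODES}")


def _finalize(rows: list[dict], adjust: str) -> pd.DataFrame:
    out = pd.DataFrame(rows)
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out["adjust_mode"] = adjust
    return out


def single_pair_screen(
    table: CountTable,
    y: OutcomeVector,
    adjust: str = "none",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-pair logistic screen of the origin-line dichotomized marker.

    For every unordered pair (i < j): the slope d_hat of the no-intercept
    regression of x_i on x_j is fitted on ALL samples (this step never sees
    the outcome); the marker W = 1(x_i > d_hat * x_j) enters a logistic model
    of y, with the pair's two main effects added on the RA or CLR scale when
    ``adjust`` is not ``"none"``. Degenerate fits (constant marker,
    separation, non-convergence) get a missing p-value and are excluded from
    the BH denominator.

    Returns a DataFrame with columns ``pair_i, pair_j, i_index, j_index,
    slope, p_value, q_value, adjust_mode, degenerate``.
    """
    yv = np.asarray(y.values, dtype=float)
    if len(np.unique(yv)) < 2:
        raise ValueError("outcome must contain both classes")
    X = table.counts.astype(float)
    adj = _adjustment_matrix(table, adjust, pseudocount)
    taxa = np.asarray(table.taxon_ids)
    rows = []
    for i, j in enumerate_pairs(table.n_taxa):
        xi, xj = X[:, i], X[:, j]
        degenerate = False
        slope = np.nan
        p = np.nan
        if float(xj @ xj) == 0.0:
            degenerate = True
        else:
            slope = fit_origin_slope(xi, xj)
            w = (xi > slope * xj).astype(float)
            if w.min() == w.max():
                degenerate = True  # constant marker carries no information
            else:
                cols = [np.ones_like(w), w]
                if adj is not None:
                    cols += [adj[:, i], adj[:, j]]
                p, degenerate = _wald_p(yv, np.column_stack(cols), col=1)
        rows.append(
            dict(
                pair_i=taxa[i], pair_j=taxa[j], i_index=i, j_index=j,
                slope=slope, p_value=p, degenerate=degenerate,
            )
        )
    return _finalize(rows, adjust)


def multiplicative_interaction_screen(
    table: CountTable,
    y: OutcomeVector,
    adjust: str = "ra",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-pair logistic screen of a standard multiplicative interaction.

    Fits y ~ x_i + x_j + x_i*x_j per pair on the RA or CLR scale and records
    the Wald p-value of the product term. Targets a different alternative
    than the dichotomized screens: a smooth interaction rather than a
    fold-change dominance switch.
    """
    if adjust not in ("ra", "clr"):
        raise ValueError("adjust must be 'ra' or 'clr'")
    yv = np.asarray(y.values, dtype=float)
    if len(np.unique(yv)) < 2:
        raise ValueError("outcome must contain both classes")
    adj = _adjustment_matrix(table, adjust, pseudocount)
    taxa = np.asarray(table.taxon_ids)
    rows = []
    for i, j in enumerate_pairs(table.n_taxa):
        ai, aj = adj[:, i], adj[:, j]
        design = np.column_stack([np.ones_like(ai), ai, aj, ai * aj])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            p, degenerate = np.nan, True
        else:
            p, degenerate = _wald_p(yv, design, col=3)
        rows.append(
            dict(
                pair_i=taxa[i], pair_j=taxa[j], i_index=i, j_index=j,
                slope=np.nan, p_value=p, degenerate=degenerate,
            )
        )
    return _finalize(rows, f"multiplicative-{adjust}")


def _origin_markers(table: CountTable) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Origin-line dichotomized markers W for every non-degenerate pair."""
    X = table.counts.astype(float)
    markers, kept = [], []
    for i, j in enumerate_pairs(table.n_taxa):
        xj = X[:, j]
        if float(xj @ xj) == 0.0:
            continue
        w = X[:, i] > fit_origin_slope(X[:, i], xj) * xj
        markers.append(w)
        kept.append((i, j))
    return np.asarray(markers, dtype=bool), kept


def overlap_logodds_diagnostic(
    table: CountTable,
    max_couples: int = 50_000,
    seed: int = 0,
) -> dict:
    """Association between pair markers that share a taxon vs those that don't.

    For couples of origin-line markers (W^{ab}, W^{cd}), computes |log OR| of
    their 2x2 cross-table (Haldane-Anscombe +0.5 when any cell is zero) and
    returns the median per class: "overlapping" ({a,b} and {c,d} share a
    taxon) vs "non-overlapping". A large overlapping median quantifies the
    correlation induced among markers built from a common taxon — the reason
    naive per-pair FDR screens over-select. Couples are subsampled beyond
    ``max_couples``.
    """
    if table.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    markers, pairs = _origin_markers(table)
    n_markers = len(pairs)
    total = n_markers * (n_markers - 1) // 2
    if total <= max_couples:
        couples = np.asarray(list(combinations(range(n_markers), 2)))
    else:
        rng = np.random.default_rng(seed)
        a = rng.integers(0, n_markers, size=2 * max_couples)
        b = rng.integers(0, n_markers, size=2 * max_couples)
        keep = a < b
        couples = np.unique(np.column_stack([a[keep], b[keep]]), axis=0)[:max_couples]
    wa = markers[couples[:, 0]]
    wb = markers[couples[:, 1]]
    n11 = (wa & wb).sum(axis=1).astype(float)
    n10 = (wa & ~wb).sum(axis=1).astype(float)
    n01 = (~wa & wb).sum(axis=1).astype(float)
    n00 = (~wa & ~wb).sum(axis=1).astype(float)
    zero = (n11 == 0) | (n10 == 0) | (n01 == 0) | (n00 == 0)
    for cells in (n11, n10, n01, n00):
        cells[zero] += 0.5
    abs_log_or = np.abs(np.log(n11 * n00) - np.log(n10 * n01))
    pair_arr = np.asarray(pairs)
    pa = pair_arr[couples[:, 0]]
    pb = pair_arr[couples[:, 1]]
    overlapping = (
        (pa[:, 0:1] == pb).any(axis=1) | (pa[:, 1:2] == pb).any(axis=1)
    )
    return {
        "median_abs_log_or_overlapping": float(np.median(abs_log_or[overlapping]))
        if overlapping.any() else np.nan,
        "median_abs_log_or_non_overlapping": float(np.median(abs_log_or[~overlapping]))
        if (~overlapping).any() else np.nan,
        "n_overlapping": int(overlapping.sum()),
        "n_non_overlapping": int((~overlapping).sum()),
    }
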