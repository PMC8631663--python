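"""Synthetic case-control microbiome data and the simulation harness.

The count generator emulates the salient features of genus-level 16S tables
from case-control studies: a few hundred samples, tens of taxa after
prevalence filtering, heavy right skew of abundances, a high fraction of
zeros that varies by taxon, and per-sample totals set by sequencing depth
rather than biology (compositionality). Counts are drawn by allocating a
random sequencing depth multinomially over zero-inflated log-normal taxon
intensities.

Outcomes are generated under three regimes:

* **alternative** — logistic model on M planted dichotomized pair
  indicators: logit(pi) = beta0 + sum_m beta_m * 1(X_m1 <= c_m * X_m2),
  with beta0 set so the empirical mean of logit(pi) is exactly zero;
* **null1** — main effects only, on the relative-abundance scale, restricted
  to taxa observed in at least 40% of samples (no pair is truly associated,
  but abundances are);
* **null2** — labels independent of the counts, Y ~ Bernoulli(0.5).

`run_experiment` wires the generators to the ranking methods and reports
average true/false positives and true-pair ranks over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from . import core, screens
from .io_tables import CountTable, OutcomeVector, relative_abundance
from .pair_engine import build_threshold_grid, dichotomize, pair_ratios, select_threshold

__all__ = [
    "ScenarioSpec",
    "ExperimentSummary",
    "synthetic_counts",
    "generate_alternative",
    "generate_null1",
    "generate_null2",
    "pick_planted_thresholds",
    "choose_low_correlation_pairs",
    "score_selection",
    "rank_truth",
    "run_experiment",
]


@dataclass
class ScenarioSpec:
    """One outcome-generation scenario.

    ``planted_pairs`` holds (i, j, c, beta) tuples for the alternative;
    ``planted_main`` holds (taxon index, beta) tuples for null1. ``kind`` is
    ``"alternative"``, ``"null1"`` or ``"null2"``.
    """

    kind: str
    planted_pairs: list[tuple[int, int, float, float]] = field(default_factory=list)
    planted_main: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("alternative", "null1", "null2"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "alternative":
            if not self.planted_pairs:
                raise ValueError("alternative scenario needs planted pairs")
            for i, j, c, _ in self.planted_pairs:
                if i == j:
                    raise ValueError("planted pair must have two distinct taxa")
                if not c > 0:
                    raise ValueError("planted thresholds must be > 0")
        if self.kind == "null1" and not self.planted_main:
            raise ValueError("null1 scenario needs planted main effects")

    @property
    def truth(self) -> list[tuple[int, int]]:
        """Canonical (i < j) unordered true pairs (empty under the nulls)."""
        return sorted({(min(i, j), max(i, j)) for i, j, _, _ in self.planted_pairs})


def synthetic_counts(
    n_samples: int = 363,
    n_taxa: int = 61,
    mean_log_abundance: np.ndarray | None = None,
    dispersion: float = 2.0,
    zero_inflation: np.ndarray | None = None,
    depth_range: tuple[int, int] = (5_000, 50_000),
    seed: int = 0,
) -> CountTable:
    """Sparse, skewed, compositional synthetic count table.

    Per sample: a sequencing depth is drawn uniformly from ``depth_range``
    and allocated multinomially over latent taxon intensities
    ``exp(mu_t + dispersion * N(0,1))``, each independently zeroed with its
    taxon's ``zero_inflation`` probability. Totals therefore equal the drawn
    depths exactly (compositionality), log-normal intensities give the heavy
    right skew, and zero inflation the sparsity.

    Defaults mirror a genus-level oral-microbiome case-control table:
    363 samples, 61 taxa, baseline log-intensities spread over ~4 nats and
    per-taxon zero-inflation ramping from 0 to 0.85 (so every taxon clears a
    10% prevalence filter while many are absent from most samples).
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not dispersion > 0:
        raise ValueError("dispersion must be > 0")
    lo, hi = depth_range
    if not (0 < lo <= hi):
        raise ValueError("depth_range must satisfy 0 < min <= max")
    if mean_log_abundance is None:
        mean_log_abundance = np.linspace(4.0, 0.0, n_taxa)
    mu = np.asarray(mean_log_abundance, dtype=float)
    if mu.shape != (n_taxa,):
        raise ValueError("mean_log_abundance must have length n_taxa")
    if zero_inflation is None:
        zero_inflation = np.linspace(0.0, 0.85, n_taxa)
    zi = np.asarray(zero_inflation, dtype=float)
    if zi.shape != (n_taxa,):
        raise ValueError("zero_inflation must have length n_taxa")
    if np.any(zi < 0) or np.any(zi >= 1):
        raise ValueError("zero_inflation entries must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    depths = rng.integers(lo, hi + 1, size=n_samples)
    intensity = np.exp(mu[None, :] + dispersion * rng.standard_normal((n_samples, n_taxa)))
    present = rng.random((n_samples, n_taxa)) >= zi[None, :]
    # a sample with every taxon zeroed cannot absorb its depth; keep the
    # least-suppressed taxon present (vanishingly rare under the defaults)
    dead = ~present.any(axis=1)
    if dead.any():
        present[dead, int(np.argmin(zi))] = True
    intensity *= present
    probs = intensity / intensity.sum(axis=1, keepdims=True)
    counts = np.empty((n_samples, n_taxa), dtype=np.int64)
    for k in range(n_samples):
        counts[k] = rng.multinomial(depths[k], probs[k])
    samples = [f"S{k + 1:04d}" for k in range(n_samples)]
    taxa = [f"taxon_{t + 1:03d}" for t in range(n_taxa)]
    return CountTable(samples, taxa, counts)


def _draw_outcome(eta_raw: np.ndarray, rng) -> tuple[OutcomeVector, dict]:
    """Center the linear predictor at zero, then draw Bernoulli labels."""
    beta0 = -float(eta_raw.mean())
    eta = beta0 + eta_raw
    pi = expit(eta)
    y = (rng.random(eta.shape[0]) < pi).astype(np.int8)
    info = {"beta0": beta0, "eta": eta, "pi": pi}
    return OutcomeVector(y, positive_label="1"), info


def generate_alternative(
    table: CountTable,
    spec: ScenarioSpec,
    seed: int = 0,
    full_output: bool = False,
):
    """Outcome from the logistic pair-indicator model.

    logit(pi_k) = beta0 + sum_m beta_m * 1(X_{m1,k} <= c_m * X_{m2,k}),
    with zero/zero samples randomized at probability one half and beta0 set
    so that the empirical mean of logit(pi) is exactly zero.
    """
    if spec.kind != "alternative":
        raise ValueError("spec.kind must be 'alternative'")
    p = table.n_taxa
    rng = np.random.default_rng(seed)
    X = table.counts
    eta_raw = np.zeros(table.n_samples)
    for i, j, c, beta in spec.planted_pairs:
        if not (0 <= i < p and 0 <= j < p):
            raise ValueError(f"planted pair ({i}, {j}) outside the table")
        z = dichotomize(X[:, i], X[:, j], c, rng=rng)
        eta_raw += beta * z
    y, info = _draw_outcome(eta_raw, rng)
    return (y, info) if full_output else y


def generate_null1(
    table: CountTable,
    spec: ScenarioSpec,
    seed: int = 0,
    min_prevalence: float = 0.4,
    full_output: bool = False,
):
    """Outcome from main effects only, on the relative-abundance scale.

    Planted taxa must be observed in at least ``min_prevalence`` of samples
    (default 40%): rare taxa give near-degenerate RA main effects, and the
    regime is meant to plant *abundance* signal with no true pair.
    """
    if spec.kind != "null1":
        raise ValueError("spec.kind must be 'null1'")
    prevalence = (table.counts > 0).mean(axis=0)
    ra = relative_abundance(table)
    eta_raw = np.zeros(table.n_samples)
    for m, beta in spec.planted_main:
        if not 0 <= m < table.n_taxa:
            raise ValueError(f"planted taxon {m} outside the table")
        if prevalence[m] < min_prevalence:
            raise ValueError(
                f"taxon {table.taxon_ids[m]!r} has prevalence "
                f"{prevalence[m]:.2f} < {min_prevalence}"
            )
        eta_raw += beta * ra[:, m]
    rng = np.random.default_rng(seed)
    y, info = _draw_outcome(eta_raw, rng)
    return (y, info) if full_output else y


def generate_null2(n_samples: int, seed: int = 0) -> OutcomeVector:
    """Labels independent of everything: Y ~ Bernoulli(0.5)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    return OutcomeVector((rng.random(n_samples) < 0.5).astype(np.int8))


def pick_planted_thresholds(
    table: CountTable,
    pairs: list[tuple[int, int]],
    y_ref: OutcomeVector | None = None,
    lo: float = 0.2,
    hi: float = 0.8,
    n_points: int = 50,
    seed: int = 0,
) -> list[float]:
    """Fold-thresholds c_m for planted pairs.

    With a reference outcome, c_m minimizes the impurity on the full data
    (the data-analysis route). Without one, c_m is the median finite count
    ratio — the induced indicator then splits the cohort roughly in half,
    which maximizes its information content. Pairs with no finite ratio fall
    back to c_m = 1.
    """
    rng = np.random.default_rng(seed)
    X = table.counts
    out = []
    for i, j in pairs:
        xi, xj = X[:, i], X[:, j]
        r = pair_ratios(xi, xj)
        finite = r[np.isfinite(r)]
        if finite.size == 0:
            out.append(1.0)
            continue
        if y_ref is not None:
            grid = build_threshold_grid(xi, xj, lo, hi, n_points)
            c, _ = select_threshold(xi, xj, y_ref.values, grid, rng=rng)
            out.append(c)
        else:
            med = float(np.median(finite))
            out.append(med if med > 0 else 1.0)
    return out


def choose_low_correlation_pairs(
    table: CountTable,
    base_pairs: list[tuple[int, int]],
    n_additional: int,
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Additional planted pairs on fresh taxa, weakly correlated with the base set.

    Candidates use taxa disjoint from every already-chosen pair; each step
    greedily picks the candidate whose median-ratio indicator minimizes the
    maximum absolute correlation with the indicators chosen so far. Used to
    extend a 2-pair scenario to 6 pairs.
    """
    rng = np.random.default_rng(seed)
    X = table.counts
    chosen = [tuple(p) for p in base_pairs]

    def indicator(i, j):
        c = pick_planted_thresholds(table, [(i, j)])[0]
        return dichotomize(X[:, i], X[:, j], c, rng=rng).astype(float)

    signals = [indicator(i, j) for i, j in chosen]
    for _ in range(n_additional):
        used = {t for p in chosen for t in p}
        best, best_score = None, np.inf
        for i in range(table.n_taxa):
            if i in used:
                continue
            for j in range(i + 1, table.n_taxa):
                if j in used:
                    continue
                z = indicator(i, j)
                if z.std() == 0:
                    continue
                cors = [
                    abs(np.corrcoef(z, s)[0, 1]) if s.std() > 0 else 0.0
                    for s in signals
                ]
                score = max(cors) if cors else 0.0
                if score < best_score:
                    best, best_score = (i, j), score
        if best is None:
            raise ValueError("no eligible candidate pair on unused taxa")
        chosen.append(best)
        signals.append(indicator(*best))
    return chosen[len(base_pairs):]


def score_selection(
    selected: list[tuple[int, int]], truth: list[tuple[int, int]]
) -> tuple[int, int]:
    """(true positives, false positives) of a selected pair set."""
    canon = lambda pairs: {(min(i, j), max(i, j)) for i, j in pairs}
    sel, tru = canon(selected), canon(truth)
    return len(sel & tru), len(sel - tru)


def rank_truth(
    pairs: list[tuple[int, int]],
    values: np.ndarray,
    truth: list[tuple[int, int]],
    higher_is_better: bool = True,
) -> tuple[dict[tuple[int, int], int], float]:
    """Competition ranks (ties -> min rank) of the true pairs in an ordering.

    ``values`` scores every pair in ``pairs``; NaN (e.g. a degenerate
    screen p-value) ranks worst. Returns per-true-pair ranks and their median.
    """
    values = np.asarray(values, dtype=float)
    if len(pairs) != values.shape[0]:
        raise ValueError("one value per pair required")
    keyed = {(min(i, j), max(i, j)): k for k, (i, j) in enumerate(pairs)}
    v = values.copy()
    worst = np.nanmin(v) - 1.0 if higher_is_better else np.nanmax(v) + 1.0
    v[np.isnan(v)] = worst if not np.isnan(worst) else 0.0
    ranks = rankdata(-v if higher_is_better else v, method="min").astype(int)
    out = {}
    for t in truth:
        key = (min(t), max(t))
        if key not in keyed:
            raise ValueError(f"true pair {key} not covered by the ordering")
        out[key] = int(ranks[keyed[key]])
    return out, float(np.median(list(out.values()))) if out else np.nan


_SCREEN_METHODS = {
    "screen_none": ("single", "none"),
    "screen_ra": ("single", "ra"),
    "screen_clr": ("single", "clr"),
    "mult_ra": ("mult", "ra"),
    "mult_clr": ("mult", "clr"),
}


@dataclass
class ExperimentSummary:
    """Operating characteristics of the compared methods.

    ``operating``: one row per (method, threshold) with average TP/FP and
    Monte-Carlo standard errors. ``ranks``: per method, mean and median of
    the per-replicate median true-pair rank (empty under the nulls).
    """

    operating: pd.DataFrame
    ranks: pd.DataFrame
    n_reps: int
    seed: int


def run_experiment(
    scenario: ScenarioSpec,
    table: CountTable,
    methods: list[str] = ("pairseek",),
    n_reps: int = 100,
    s_thresholds: tuple[float, ...] = (0.7, 0.8, 0.9),
    fdr_levels: tuple[float, ...] = (0.05, 0.01, 0.001, 0.0001),
    B: int = 500,
    seed: int = 0,
    pairseek_kwargs: dict | None = None,
) -> ExperimentSummary:
    """Replicated operating-characteristics experiment on fixed covariates.

    The count table is held fixed (the covariates play the role of an
    observed cohort); only the outcome is redrawn each replicate from the
    scenario's generative model. Each method is run per replicate and scored
    against the planted truth: the stability-selection ranking at each
    dominance threshold, the screens at each FDR level. Failures inside a
    replicate propagate — they are not silently dropped.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    for m in methods:
        if m != "pairseek" and m not in _SCREEN_METHODS:
            raise ValueError(f"unknown method {m!r}")
    truth = scenario.truth
    pairseek_kwargs = dict(pairseek_kwargs or {})
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s) for s in ss.generate_state(2 * n_reps, dtype=np.uint32)]

    tp: dict[tuple[str, float], list[int]] = {}
    fp: dict[tuple[str, float], list[int]] = {}
    med_ranks: dict[str, list[float]] = {m: [] for m in methods}

    for rep in range(n_reps):
        gen_seed, method_seed = rep_seeds[2 * rep], rep_seeds[2 * rep + 1]
        if scenario.kind == "alternative":
            y = generate_alternative(table, scenario, seed=gen_seed)
        elif scenario.kind == "null1":
            y = generate_null1(table, scenario, seed=gen_seed)
        else:
            y = generate_null2(table.n_samples, seed=gen_seed)

        for method in methods:
            if method == "pairseek":
                dom = core.pairseek(
                    table, y, B=B, seed=method_seed, **pairseek_kwargs
                )
                pairs = list(zip(dom["i_index"], dom["j_index"]))
                for thr in s_thresholds:
                    sel = [
                        (i, j)
                        for i, j, s in zip(dom["i_index"], dom["j_index"],
                                           dom["dominance_score"])
                        if s >= thr
                    ]
                    t, f = score_selection(sel, truth)
                    tp.setdefault((method, thr), []).append(t)
                    fp.setdefault((method, thr), []).append(f)
                if truth:
                    _, med = rank_truth(
                        pairs, dom["dominance_score"].to_numpy(), truth
                    )
                    med_ranks[method].append(med)
            else:
                kind, adjust = _SCREEN_METHODS[method]
                if kind == "single":
                    res = screens.single_pair_screen(table, y, adjust=adjust)
                else:
                    res = screens.multiplicative_interaction_screen(
                        table, y, adjust=adjust
                    )
                pairs = list(zip(res["i_index"], res["j_index"]))
                q = res["q_value"].to_numpy()
                for lvl in fdr_levels:
                    sel = [
                        pr for pr, qv in zip(pairs, q)
                        if not np.isnan(qv) and qv <= lvl
                    ]
                    t, f = score_selection(sel, truth)
                    tp.setdefault((method, lvl), []).append(t)
                    fp.setdefault((method, lvl), []).append(f)
                if truth:
                    _, med = rank_truth(
                        pairs, res["p_value"].to_numpy(), truth,
                        higher_is_better=False,
                    )
                    med_ranks[method].append(med)

    rows = []
    for (method, thr), tps in sorted(tp.items()):
        fps = fp[(method, thr)]
        tps, fps = np.asarray(tps, float), np.asarray(fps, float)
        rows.append(
            dict(
                method=method,
                threshold=thr,
                avg_tp=tps.mean(),
                avg_fp=fps.mean(),
                se_tp=tps.std(ddof=1) / np.sqrt(n_reps) if n_reps > 1 else np.nan,
                se_fp=fps.std(ddof=1) / np.sqrt(n_reps) if n_reps > 1 else np.nan,
                n_reps=n_reps,
            )
        )
    operating = pd.DataFrame(rows)
    rank_rows = [
        dict(
            method=m,
            mean_median_rank=float(np.mean(v)) if v else np.nan,
            median_median_rank=float(np.median(v)) if v else np.nan,
            n_reps=len(v),
        )
        for m, v in med_ranks.items()
        if truth
    ]
    ranks = pd.DataFrame(rank_rows)
    return ExperimentSummary(operating=operating, ranks=ranks, n_reps=n_reps, seed=seed)
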