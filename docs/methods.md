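# Methods

## Problem and model

Case-control amplicon-sequencing studies (16S rRNA, counts aggregated to
genus or another taxonomic level) produce samples × taxa tables of raw read
counts that are sparse, heavily right-skewed, and compositional: the
per-sample total is set by sequencing depth, not biology. `pairseek` looks
for *pairs* of taxa whose relative balance differs between cases and
controls — situations where, say, cases tend to carry taxon *i* at most
*c*-fold above taxon *j* while controls show the opposite.

The pair relationship is dichotomized within each sample:

    Z_k^{ij}(c) = 1( X_ik <= c * X_jk )

with *c* a positive fold-threshold. Because both counts come from the same
sample, Z depends only on the ratio X_i/X_j; depth cancels and no
normalization is required, which also makes the statistic robust to skew.
Samples with X_ik = X_jk = 0 carry no ratio information and are randomized
to 0/1 with probability one half.

## Dominance score

The ranking statistic is a stability-selection quantity. On each of B
iterations:

1. Split the n samples at random into an analysis half D (size ⌊n/2⌋) and a
   held-out half D*; redraw (up to 100 times) if either half lacks a class.
2. Orient each unordered pair at random — Z^{ij} and Z^{ji} are not
   complementary in general, so one orientation per pair per iteration
   removes the redundancy while keeping the procedure order-invariant on
   average.
3. On D*, choose the pair's threshold c by minimizing the weighted
   two-branch Gini impurity γ·p1(1−p1) + (1−γ)·p2(1−p2) of the case split
   induced by Z(c), scanned over a grid of 50 equally spaced values between
   the 20th and 80th percentiles of the pair's observed ratios. Choosing c
   out-of-sample avoids the overfitting that an in-sample,
   outcome-optimized threshold would cause.
4. On D, build the matrix of all pair indicators at their selected
   thresholds and fit an L1-penalized logistic regression
   (−(1/|D|)·loglik + λ‖β‖₁, intercept unpenalized, predictors left as raw
   0/1 indicators) at a penalty λ drawn uniformly from a 100-point grid
   between λ_max (the smallest penalty with an empty fitted support,
   computed in closed form from the KKT conditions on the iteration's own
   design) and 0.001·λ_max. Randomizing λ replaces the error-control tuning
   of classical stability selection, whose exchangeability assumptions the
   correlated pair indicators violate.

The dominance score S_ij is the fraction of iterations in which pair {i, j}
kept a nonzero coefficient; pairs with S_ij above a prespecified threshold
S_thr (0.7–0.9 in practice) are flagged as candidate signals. Scores have
resolution 1/B and Monte-Carlo standard error ≈ √(S(1−S)/B).

## Comparator screens

The natural simple alternative fits one logistic regression per pair on a
marker dichotomized without looking at the outcome: W = 1(X_i > d̂·X_j)
with d̂ the no-intercept least-squares slope of x_i on x_j (d̂ = Σx_i x_j /
Σx_j²), optionally adjusting for the two taxa's main effects on the
relative-abundance or CLR scale, with Benjamini–Hochberg correction across
pairs. A multiplicative-interaction variant (y ~ x_i + x_j + x_i·x_j on RA
or CLR) targets a smooth interaction instead of a fold-change switch. These
screens over-select because any one taxon participates in p−1 markers: the
package's overlap diagnostic quantifies the induced dependence as the
median |log OR| between markers sharing a taxon versus markers on disjoint
taxa (Haldane–Anscombe +0.5 correction when a 2×2 cell is empty).

## Synthetic data

The generator emulates the shape of a genus-level case-control table
(defaults: 363 samples × 61 taxa). Per sample, a sequencing depth is drawn
uniformly from 5,000–50,000 reads and allocated multinomially over latent
taxon intensities exp(μ_t + σ·N(0,1)), each zeroed independently with a
per-taxon probability. Defaults: baseline log-intensities μ spread linearly
over 4 nats (abundances spanning ~two orders of magnitude), log-normal
σ = 2 (heavy right skew), zero-inflation ramping linearly from 0 to 0.85 so
prevalence ranges from ~15% to ~100% and every taxon clears the standard
10% prevalence filter. Compositionality, sparsity and skew hold by
construction. What the generator does **not** emulate: phylogenetic
correlation between taxa, taxon-taxon ecological dependence beyond the
shared multinomial constraint, batch effects, or overdispersion structure
tied to real primers — so passing tests demonstrate the method's operating
characteristics under a realistic marginal shape, not performance on any
particular real cohort.

Outcomes come from three regimes. *Alternative*: logit(π) = β₀ +
Σ_m β_m·1(X_{m1} ≤ c_m·X_{m2}) over M planted pairs, with β₀ set so the
empirical mean of logit(π) is exactly zero (machine precision; audited in
tests) and Y ~ Bernoulli(π). Default effect sizes for M = 2 are
β = (2.56, 2.28). *Null 1* plants main effects only (β = −0.7 per taxon on
the relative-abundance scale, taxa restricted to ≥ 40% prevalence): real
abundance signal, no true pair. *Null 2* draws labels Bernoulli(0.5)
independent of everything.

Planted thresholds c_m: when a reference outcome exists, c_m is chosen by
the same impurity search used in the analysis; without one (the synthetic
default) c_m is the median finite ratio, which puts the indicator's
prevalence near one half and maximizes its information content. Extending
M = 2 to M = 6 uses a greedy search over pairs on unused taxa minimizing
the maximum absolute correlation of the new indicator with those already
planted.

## Numerical choices

- **Ratio-scale comparisons.** Z is evaluated as X_i/X_j ≤ c rather than
  X_i ≤ c·X_j. The two are equivalent in exact arithmetic; on the ratio
  scale, rescaling a sample's integer counts by an integer constant leaves
  every ratio bit-identical in IEEE arithmetic, so the whole pipeline is
  exactly depth-invariant (tested at the bit level).
- **Threshold grid.** Quantiles use linear interpolation between order
  statistics. Ratios with X_j = 0 are infinite and excluded from the
  quantile computation (the indicator handles them naturally: Z = 0 for any
  finite c); 0/0 ratios are excluded as undefined. Degenerate grids fall
  back to {1}; non-positive grid values (possible when many ratios are
  zero) are dropped. Ties in the impurity scan resolve to the smallest c.
- **λ grid spacing** is logarithmic by default ("equally spaced" on the log
  scale, the standard path construction), with a linear option. λ_max is
  recomputed on each iteration's design, since the design changes with
  every subsample and threshold selection.
- **Solver.** The L1 logistic fits use liblinear with C = 1/(nλ). liblinear
  cannot leave the intercept fully unpenalized; an intercept scaling of 100
  makes the effective intercept penalty |β₀|/100, negligible here because
  centered outcome generation keeps the true intercept near zero (a tighter
  scaling costs ~2–10× in runtime). At and above λ_max the all-zero
  solution is returned analytically from the KKT conditions rather than
  from the solver, which can wobble at that exact boundary. An
  objective-value test against an independent proximal-gradient solver
  bounds the residual solver gap below 1e-6 at tight tolerance.
- **Randomness.** One master seed drives everything. Per-pair and
  per-sample substreams (orientation, zero/zero randomization) come from a
  counter-based hash keyed by iteration number and by the *names* of the
  taxa and samples, so permuting the columns of the input table permutes
  the output without changing scores (up to solver path effects, bounded by
  ~1–2 iterations in B); subsampling and λ draws come from a PCG64
  generator. Fixed seed ⇒ bit-identical output.
- **Degenerate fits** in the screens (constant marker, separation,
  non-convergence, |coef| > 10³) record a missing p-value and are excluded
  from the BH denominator rather than imputed.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `B` | 500 | stability iterations; score resolution 1/B |
| `s_thr` | 0.8 | dominance threshold flagging candidates |
| `lo_quantile, hi_quantile` | 0.2, 0.8 | ratio quantiles bounding the c grid |
| `c_grid_points` | 50 | thresholds scanned per pair per iteration |
| `grid_size` | 100 | λ grid length |
| `min_ratio` | 0.001 | λ_min / λ_max |
| `min_prevalence` | 0.10 | outcome-blind taxon filter |
| `pseudocount` | 1 | added to counts before CLR (zeros dominate raw tables) |

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full pipeline at reduced
Monte-Carlo depth chosen as sensible desk-scale settings: planted-pair
recovery uses 20 replicates at B = 200 (acceptance script: 10 replicates at
B = 150) on a 360 × 61 cohort; the null-control run uses 20 replicates at
B = 100; single deep runs use B = 300. Monte-Carlo standard errors are
reported alongside all averaged operating characteristics so the precision
of the scaled-down estimates is visible.

## Known limitations

- The dominance score ranks pairs; it carries no formal error-control
  guarantee (the exchangeability needed for stability-selection bounds
  fails for overlapping pair markers), so S_thr is an informal cutoff.
- With p ≫ n, a single LASSO fit selects at most |D| variables, capping how
  many pairs can score highly in any one iteration.
- The method is cross-sectional: it detects differential balance at one
  time point, not directional competition dynamics.
- The CLR adjustment depends on an arbitrary pseudocount for zeros; screen
  results under CLR should be read with that sensitivity in mind.
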