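# pairseek

Rank pairs of bacterial taxa whose *dichotomized* abundance relationship
differs between binary outcome groups (case vs control) in amplicon-
sequencing count tables.

Single-taxon differential-abundance tools ignore the ecology of the
microbiome, where taxa cooperate and compete; naive per-pair tests drown in
the correlation that p taxa induce among their p(p−1)/2 pair markers.
`pairseek` targets a specific, interpretable signal — in cases, taxon *i*
is at most *c*-fold above taxon *j*, in controls the opposite — and ranks
all pairs with a resampling statistic that is robust to the sparsity, skew
and compositionality of 16S count data.

## The statistic

For taxa *i*, *j* and fold-threshold *c* > 0, each sample contributes a
binary indicator

> Z_k^{ij}(c) = **1**(X_ik ≤ c · X_jk),

a within-sample ratio comparison, so sequencing depth cancels and no
normalization is needed (samples with both counts zero are randomized at
probability ½). Over B stability iterations the samples are split in half;
*c* is tuned on the held-out half by minimizing the Gini-style impurity
γ·p₁(1−p₁) + (1−γ)·p₂(1−p₂) of the induced case split over a grid spanning
the 20th–80th percentiles of the observed ratios; and an L1-penalized
logistic regression of the outcome on *all* pair indicators is fitted on
the analysis half at a penalty λ drawn at random from a 100-point grid
below λ_max. The **dominance score**

> S_ij = (1/B) Σ_b **1**(pair i,j has a nonzero coefficient in fit b)

ranks the pairs; S_ij ≥ S_thr (typically 0.7–0.9) flags candidates. The
package also ships the comparator per-pair logistic screens (origin-line
dichotomization, RA/CLR main-effect adjustment, BH-FDR, multiplicative-
interaction variant), a synthetic cohort generator, and a replicated
simulation harness. See `docs/methods.md` for the full model description.

## Worked example

```python
import pairseek as ps

table = ps.synthetic_counts(n_samples=120, n_taxa=12, seed=21)
c = ps.pick_planted_thresholds(table, [(1, 7)])[0]
spec = ps.ScenarioSpec("alternative", planted_pairs=[(1, 7, c, 2.5)])
y = ps.generate_alternative(table, spec, seed=22)
dominance = ps.pairseek(table, y, B=200, s_thr=0.8, seed=23)
print(dominance.head(3)[["pair_i", "pair_j", "dominance_score", "selected"]]
      .to_string(index=False))
```

prints

```
   pair_i    pair_j  dominance_score  selected
taxon_002 taxon_008            0.835      True
taxon_011 taxon_012            0.600     False
taxon_001 taxon_005            0.580     False
```

The planted pair (taxon_002/taxon_008, effect β = 2.5 on the log-odds
scale) kept a nonzero LASSO coefficient in 83.5% of the 200 half-sample
fits and is the only pair selected at S_thr = 0.8; the best unplanted pair
reaches 0.60. Longer scripts — the comparator screens, the overlap
diagnostic, and a small operating-characteristics study — live in
`examples/`, one capability per file.

The same analysis runs from the shell on TSV inputs:

```bash
pairseek run --counts counts.tsv --metadata meta.tsv \
  --outcome-col status --positive-label case --B 500 --seed 1 --out dom.tsv
```

(`pairseek screen` for the comparator screens, `pairseek simulate` for
scenario experiments from a YAML config, `pairseek make-fixtures` for toy
inputs; each output comes with a JSON manifest of parameters, seed and
input checksums.)

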