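"""Rank taxon pairs by dominance score on a small synthetic cohort.

Builds a 120-sample, 12-taxon count table, plants one true pair relationship
(cases tend to have taxon_002 at most c-fold above taxon_008, controls the
opposite), and runs the stability-selection ranking.
"""

import pairseek as ps

table = ps.synthetic_counts(n_samples=120, n_taxa=12, seed=21)
c = ps.pick_planted_thresholds(table, [(1, 7)])[0]
spec = ps.ScenarioSpec("alternative", planted_pairs=[(1, 7, c, 2.5)])
y = ps.generate_alternative(table, spec, seed=22)
print(f"cohort: {table.n_samples} samples x {table.n_taxa} taxa, "
      f"{int(y.values.sum())} cases; planted pair taxon_002/taxon_008 "
      f"at c = {c:.2f}")

dominance = ps.pairseek(table, y, B=200, s_thr=0.8, seed=23)
print("\ntop 5 of", len(dominance), "pairs:")
print(dominance.head(5)[["pair_i", "pair_j", "dominance_score",
                         "median_c", "selected"]].to_string(index=False))

# The dominance score is the fraction of B half-sample LASSO fits in which
# the pair's fold-change indicator kept a nonzero coefficient; the planted
# pair should sit at or near the top with a score well above the 0.8
# selection threshold, while unplanted pairs stay low.
hits = ps.rank_and_select(dominance, 0.8)
print(f"\n{len(hits)} pair(s) selected at S >= 0.8")
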