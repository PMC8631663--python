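"""File-based workflow: write a cohort to disk, filter, transform, reload.

Mirrors what the command-line interface does internally; useful when counts
arrive as TSV exports from an amplicon pipeline.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

import pairseek as ps

workdir = Path(tempfile.mkdtemp())
table = ps.synthetic_counts(n_samples=80, n_taxa=25, seed=91)
y = ps.generate_null2(80, seed=92)

counts_path = workdir / "counts.tsv"
meta_path = workdir / "metadata.tsv"
ps.write_count_table(table, counts_path)
pd.DataFrame({
    "sample_id": table.sample_ids,
    "status": np.where(y.values == 1, "case", "control"),
}).to_csv(meta_path, sep="\t", index=False)

reloaded = ps.read_count_table(counts_path)
assert reloaded == table
outcome = ps.read_outcome(meta_path, "status", "case",
                          sample_ids=reloaded.sample_ids)
print(f"round-tripped {reloaded.n_samples} samples x {reloaded.n_taxa} taxa; "
      f"{int(outcome.values.sum())} cases")

filtered = ps.prevalence_filter(reloaded, 0.10)
print(f"prevalence filter at 10%: {reloaded.n_taxa} -> {filtered.n_taxa} taxa")

ra = ps.relative_abundance(filtered)
clr = ps.clr_transform(filtered, pseudocount=1.0)
print(f"relative abundance rows sum to 1 (max dev {abs(ra.sum(1) - 1).max():.1e}); "
      f"CLR rows sum to 0 (max dev {abs(clr.sum(1)).max():.1e})")
print(f"\nequivalent shell command:\n  pairseek run --counts {counts_path} "
      f"--metadata {meta_path} --outcome-col status --positive-label case "
      f"--B 200 --seed 1 --out dominance.tsv")
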