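"""Count-table and outcome I/O, prevalence filtering, and compositional transforms.

The central container is :class:`CountTable`: a samples × taxa matrix of raw
(non-normalized) sequencing read counts, as produced by amplicon pipelines
after taxonomic aggregation. Outcomes are binary case/control labels aligned
to the table's samples.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "OutcomeVector",
    "read_count_table",
    "write_count_table",
    "read_outcome",
    "prevalence_filter",
    "relative_abundance",
    "clr_transform",
]


def _check_unique(labels, what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dups = sorted(set(seen[seen.duplicated()]))
        raise ValueError(f"duplicate {what} labels: {dups}")


@dataclass
class CountTable:
    """Samples × taxa matrix of non-negative integer read counts.

    Parameters
    ----------
    sample_ids, taxon_ids
        Unique string labels for rows and columns.
    counts
        Integer array of shape ``(n_samples, n_taxa)``.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.taxon_ids, "taxon")
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"({len(self.sample_ids)} samples, {len(self.taxon_ids)} taxa)"
            )
        if counts.size and np.any(~np.isfinite(counts.astype(float))):
            raise ValueError("counts contain non-finite values")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        as_int = counts.astype(np.int64)
        if not np.array_equal(as_int, counts.astype(float)):
            raise ValueError("counts must be integer-valued")
        self.counts = as_int

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CountTable)
            and self.sample_ids == other.sample_ids
            and self.taxon_ids == other.taxon_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class OutcomeVector:
    """Binary case/control labels (case = 1) aligned to a table's samples."""

    values: np.ndarray
    positive_label: str = "1"

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 1:
            raise ValueError("outcome must be a 1-D vector")
        if not np.all(np.isin(values, (0, 1))):
            raise ValueError("outcome entries must all be 0 or 1")
        self.values = values.astype(np.int8)

    def __len__(self) -> int:
        return len(self.values)


def _sep_for(path: str) -> str:
    return "," if os.path.splitext(str(path))[1].lower() == ".csv" else "\t"


def read_count_table(path, orientation: str = "samples-as-rows") -> CountTable:
    """Read a delimited count table (TSV default, CSV by extension).

    The first column holds row labels and the header holds column labels.
    ``orientation`` says what the rows are: ``"samples-as-rows"`` (default)
    or ``"taxa-as-rows"``, in which case the table is transposed.
    """
    if orientation not in ("samples-as-rows", "taxa-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split(sep)
    _check_unique(header[1:], "header")  # pandas would silently rename dups
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "taxa-as-rows":
        df = df.T
    _check_unique(df.index, "sample")
    _check_unique(df.columns, "taxon")
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce")
            if bad.isna().any():
                row = df.index[int(np.where(bad.isna())[0][0])]
                raise ValueError(
                    f"non-numeric cell at row {row!r}, column {col!r} in {path}"
                )
        values = df.astype(float).to_numpy()
    if np.any(values < 0):
        raise ValueError(f"negative count in {path}")
    return CountTable(list(df.index), list(df.columns), values)


def write_count_table(table: CountTable, path) -> None:
    table.to_dataframe().to_csv(path, sep=_sep_for(path), index_label="sample_id")


def read_outcome(
    path,
    outcome_col: str,
    positive_label: str,
    sample_ids: list[str] | None = None,
    sample_col: str | None = None,
) -> OutcomeVector:
    """Read a binary outcome column from a metadata table.

    ``sample_col`` names the sample-ID column (default: first column). When
    ``sample_ids`` is given the metadata is aligned to that order and missing
    samples are an error.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    if outcome_col not in df.columns:
        raise ValueError(
            f"outcome column {outcome_col!r} not found in {path}; "
            f"available: {list(df.columns)}"
        )
    key = sample_col if sample_col is not None else df.columns[0]
    df[key] = df[key].astype(str)
    if sample_ids is not None:
        indexed = df.set_index(key)
        missing = [s for s in sample_ids if s not in indexed.index]
        if missing:
            raise ValueError(f"metadata missing samples: {missing[:5]}")
        labels = indexed.loc[list(sample_ids), outcome_col]
    else:
        labels = df[outcome_col]
    values = (labels.astype(str) == str(positive_label)).to_numpy().astype(np.int8)
    observed = set(labels.astype(str))
    if str(positive_label) not in observed:
        raise ValueError(
            f"positive label {positive_label!r} never occurs in column "
            f"{outcome_col!r} (observed: {sorted(observed)})"
        )
    return OutcomeVector(values, positive_label=str(positive_label))


def prevalence_filter(table: CountTable, min_prevalence: float) -> CountTable:
    """Drop taxa observed (count > 0) in fewer than ``min_prevalence`` of samples.

    Outcome-blind by construction: the operation never sees the labels.
    A taxon observed in exactly ``min_prevalence`` of samples is kept.
    """
    if not 0.0 < min_prevalence <= 1.0:
        raise ValueError("min_prevalence must be in (0, 1]")
    prevalence = (table.counts > 0).mean(axis=0)
    keep = prevalence >= min_prevalence
    if not keep.any():
        raise ValueError(
            f"no taxon reaches prevalence {min_prevalence}; "
            "lower the threshold"
        )
    taxa = [t for t, k in zip(table.taxon_ids, keep) if k]
    return CountTable(list(table.sample_ids), taxa, table.counts[:, keep])


def relative_abundance(table: CountTable) -> np.ndarray:
    """Per-sample count fractions; each row sums to 1."""
    totals = table.counts.sum(axis=1)
    zero = np.where(totals == 0)[0]
    if zero.size:
        raise ValueError(
            f"sample(s) with zero total count: {[table.sample_ids[i] for i in zero]}"
        )
    return table.counts / totals[:, None]


def clr_transform(table: CountTable, pseudocount: float = 1.0) -> np.ndarray:
    """Centered log-ratio transform of ``counts + pseudocount``.

    Each row of the result sums to zero. The pseudocount (default 1) handles
    the zeros that dominate sparse amplicon tables while preserving the
    within-sample ordering of counts.
    """
    if not pseudocount > 0:
        raise ValueError("pseudocount must be > 0")
    logs = np.log(table.counts + float(pseudocount))
    return logs - logs.mean(axis=1, keepdims=True)
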