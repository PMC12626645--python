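"""Input/output and taxon filtering.

The universal substrate of the pipeline is the :class:`CountTable`, a sample
x taxon matrix of non-negative integer read counts (ZOTU/OTU counts from an
amplicon workflow).  Tables travel on disk as TSV with taxa as rows and
samples as columns, the orientation most amplicon pipelines emit; trees are
Newick; metadata and environmental covariates are plain TSV.

Taxon inclusion follows the screening rule used for co-occurrence network
construction: a taxon is retained when its mean relative abundance exceeds
0.1% AND it occurs in strictly more than one third of the samples.  Both
thresholds are exposed as parameters.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import EmptyResultError, InvalidInputError, ParseError

__all__ = [
    "CountTable",
    "SampleMetadata",
    "read_count_table",
    "read_metadata",
    "read_tree",
    "relative_abundance",
    "filter_taxa",
]


@dataclass(frozen=True)
class CountTable:
    """Sample x taxon non-negative integer count matrix.

    Parameters
    ----------
    counts
        2-D integer array of shape ``(n_samples, n_taxa)``.
    sample_ids, taxon_ids
        Unique ordered labels for rows and columns.
    """

    counts: np.ndarray
    sample_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise InvalidInputError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise InvalidInputError("counts must be finite integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise InvalidInputError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "taxon_ids", tuple(str(t) for t in self.taxon_ids))
        n, m = counts.shape
        if len(self.sample_ids) != n or len(self.taxon_ids) != m:
            raise InvalidInputError("id lengths do not match matrix shape")
        if len(set(self.sample_ids)) != n:
            raise InvalidInputError("duplicate sample ids")
        if len(set(self.taxon_ids)) != m:
            raise InvalidInputError("duplicate taxon ids")
        if n < 2 or m < 2:
            raise InvalidInputError("need at least 2 samples and 2 taxa")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, samples_as_rows: bool = True) -> "CountTable":
        if not samples_as_rows:
            df = df.T
        return cls(df.to_numpy(), tuple(map(str, df.index)), tuple(map(str, df.columns)))

    def to_dataframe(self) -> pd.DataFrame:
        """Samples as rows, taxa as columns."""
        return pd.DataFrame(
            self.counts.copy(), index=list(self.sample_ids), columns=list(self.taxon_ids)
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(self.counts[idx], tuple(sample_ids), self.taxon_ids)

    def select_taxa(self, taxon_ids: Sequence[str]) -> "CountTable":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return CountTable(self.counts[:, idx], self.sample_ids, tuple(taxon_ids))

    def write_tsv(self, path: str | Path) -> None:
        """Write as TSV with taxa as rows and samples as columns."""
        self.to_dataframe().T.to_csv(path, sep="\t", index_label="taxon_id")


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample group labels and optional covariates."""

    table: pd.DataFrame
    group_column: str = "group"

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise InvalidInputError("duplicate sample ids in metadata")
        if self.group_column not in self.table.columns:
            raise InvalidInputError(f"metadata lacks group column {self.group_column!r}")

    def groups_for(self, sample_ids: Sequence[str]) -> pd.Series:
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise InvalidInputError(f"samples missing from metadata: {missing[:5]}")
        return self.table.loc[list(sample_ids), self.group_column]


def read_count_table(path: str | Path, taxa_as_rows: bool = True) -> CountTable:
    """Read a TSV count table.

    Default orientation is taxa as rows and samples as columns (first column
    holds taxon ids, header row holds sample ids); pass
    ``taxa_as_rows=False`` for the transpose.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse count table {path}: {exc}") from exc
    if df.empty:
        raise ParseError(f"count table {path} is empty")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(
            f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    arr = numeric.to_numpy()
    if np.any(arr != np.floor(arr)):
        r, c = np.argwhere(arr != np.floor(arr))[0]
        raise ParseError(
            f"non-integer count at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if np.any(arr < 0):
        r, c = np.argwhere(arr < 0)[0]
        raise ParseError(
            f"negative count at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    try:
        return CountTable.from_dataframe(numeric.astype(np.int64), samples_as_rows=not taxa_as_rows)
    except InvalidInputError as exc:
        raise ParseError(str(exc)) from exc


def read_metadata(path: str | Path, group_column: str = "group") -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.map(str)
    return SampleMetadata(df, group_column)


def read_tree(source: str | Path, taxa: Sequence[str] | None = None) -> dendropy.Tree:
    """Read a rooted Newick tree; optionally check that ``taxa`` are all tips."""
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:
        raise ParseError(f"cannot parse Newick tree: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ParseError("duplicate tip labels in tree")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ParseError("negative branch length in tree")
    if taxa is not None:
        missing = sorted(set(taxa) - set(labels))
        if missing:
            raise InvalidInputError(f"taxa missing from tree: {missing[:10]}")
    return tree


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Per-sample relative abundances; each row sums to 1."""
    totals = table.counts.sum(axis=1)
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        raise InvalidInputError(
            f"sample {table.sample_ids[zero[0]]!r} has zero total count"
        )
    rel = table.counts / totals[:, None]
    return pd.DataFrame(rel, index=list(table.sample_ids), columns=list(table.taxon_ids))


def filter_taxa(
    table: CountTable,
    min_mean_rel_abund: float = 0.001,
    min_prevalence: float = 1.0 / 3.0,
    abundance_statistic: str = "mean",
) -> CountTable:
    """Apply the network-stage inclusion screen.

    A taxon is retained when its across-sample mean (or, with
    ``abundance_statistic="max"``, maximum) relative abundance is strictly
    greater than ``min_mean_rel_abund`` AND the fraction of samples in which
    it occurs (count > 0) is strictly greater than ``min_prevalence``.
    Sample set and retained-taxon order are unchanged.
    """
    if abundance_statistic not in ("mean", "max"):
        raise InvalidInputError("abundance_statistic must be 'mean' or 'max'")
    rel = relative_abundance(table).to_numpy()
    stat = rel.mean(axis=0) if abundance_statistic == "mean" else rel.max(axis=0)
    prevalence = (table.counts > 0).mean(axis=0)
    keep = (stat > min_mean_rel_abund) & (prevalence > min_prevalence)
    kept = [t for t, k in zip(table.taxon_ids, keep) if k]
    if len(kept) == 0:
        raise EmptyResultError("all taxa removed by the abundance/prevalence screen")
    if len(kept) < 2:
        raise EmptyResultError("fewer than 2 taxa survive the screen")
    return table.select_taxa(kept)
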