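"""Count-matrix I/O, validation, filtering and subsetting.

Raw gene-level counts live in a :class:`CountMatrix` (genes x samples,
non-negative integers, unique IDs on both axes).  Normalized values are a
different type (:mod:`uqpgq2.normalization`) and never round-trip through
this one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CountDataError",
    "CountMatrix",
    "read_count_matrix",
    "read_htseq_counts",
    "read_sample_sheet",
    "read_gene_list",
    "filter_all_zero_genes",
    "subset_genes",
]


class CountDataError(ValueError):
    """Invalid count data or sample metadata."""


@dataclass(frozen=True)
class CountMatrix:
    """Gene-by-sample matrix of raw integer read counts.

    Parameters
    ----------
    counts : pandas.DataFrame
        Genes on the index, samples on the columns, integer cells.
        Validated on construction: unique IDs, non-negative integral values.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise CountDataError(f"duplicate gene IDs: {dups[:10]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise CountDataError(f"duplicate sample IDs: {dups[:10]}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                bad = np.argwhere((values != np.floor(values)) | ~np.isfinite(values))
                g, s = bad[0]
                raise CountDataError(
                    f"non-integer count for gene {df.index[g]!r}, sample {df.columns[s]!r}"
                )
            object.__setattr__(self, "counts", df.astype(np.int64))
            values = self.counts.to_numpy()
        if values.size and values.min() < 0:
            g, s = np.argwhere(values < 0)[0]
            raise CountDataError(
                f"negative count for gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def select_samples(self, sample_ids) -> "CountMatrix":
        """Restrict to the given samples, in the given order."""
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise CountDataError(f"unknown sample IDs: {missing}")
        return CountMatrix(self.counts.loc[:, list(sample_ids)])

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_count_matrix(path, strip_gene_version: bool = False) -> CountMatrix:
    """Read a TSV count matrix (header of sample IDs, first column gene IDs).

    Cells must be non-negative integers; a bad cell raises
    :class:`CountDataError` naming the offending gene and sample.
    ``strip_gene_version`` removes a trailing ``.N`` from gene IDs
    (off by default to avoid silent ID collisions).
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    if strip_gene_version:
        raw.index = raw.index.str.replace(r"\.\d+$", "", regex=True)
    parsed = {}
    for col in raw.columns:
        num = pd.to_numeric(raw[col], errors="coerce")
        if num.isna().any():
            gene = raw.index[int(np.argmax(num.isna().to_numpy()))]
            raise CountDataError(
                f"unparseable count for gene {gene!r}, sample {col!r}"
            )
        parsed[col] = num
    df = pd.DataFrame(parsed, index=raw.index)
    return CountMatrix(df)


def read_htseq_counts(paths, sample_ids) -> CountMatrix:
    """Assemble a CountMatrix from per-sample htseq-count two-column files.

    All files must cover the same gene universe.  Summary rows whose ID
    starts with ``__`` (``__no_feature``, ``__ambiguous``, ...) are dropped.
    """
    paths = list(paths)
    sample_ids = list(sample_ids)
    if len(paths) != len(sample_ids):
        raise CountDataError(
            f"{len(paths)} files but {len(sample_ids)} sample IDs"
        )
    columns = {}
    universe = None
    for path, sid in zip(paths, sample_ids):
        col = pd.read_csv(
            path, sep="\t", header=None, names=["gene_id", "count"], dtype={0: str}
        ).set_index("gene_id")["count"]
        genes = set(col.index)
        if universe is None:
            universe, first_order = genes, col.index
        elif genes != universe:
            diff = len(genes.symmetric_difference(universe))
            raise CountDataError(
                f"gene universe of {path} differs from the first file "
                f"(symmetric difference: {diff} IDs)"
            )
        columns[sid] = col
    df = pd.DataFrame({s: columns[s].reindex(first_order) for s in sample_ids})
    df = df.loc[~df.index.str.startswith("__")]
    return CountMatrix(df)


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a CSV sample sheet with columns ``sample_id,group``."""
    df = pd.read_csv(path, dtype=str)
    expected = {"sample_id", "group"}
    if not expected.issubset(df.columns):
        raise CountDataError(
            f"sample sheet must have columns {sorted(expected)}, got {list(df.columns)}"
        )
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise CountDataError(f"duplicate sample IDs in sheet: {dups}")
    return df[["sample_id", "group"]]


def read_gene_list(path) -> list[str]:
    """Read a plain-text gene-ID list, one per line; '#' starts a comment."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.append(line)
    return ids


def filter_all_zero_genes(m: CountMatrix) -> tuple[CountMatrix, int]:
    """Drop genes with zero counts across every sample.

    Returns the filtered matrix and the number of genes removed.  Applied
    once, jointly across all loaded samples; idempotent.
    """
    keep = m.values.sum(axis=1) > 0
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        warnings.warn("all genes have zero counts in every sample", stacklevel=2)
    return CountMatrix(m.counts.loc[keep]), n_removed


def subset_genes(m: CountMatrix, keep) -> tuple[CountMatrix, int]:
    """Restrict to genes in ``keep`` (e.g. protein-coding IDs), preserving order.

    Returns the subset and the number of requested IDs absent from the
    matrix.  An empty intersection is an error.
    """
    keep = set(keep)
    mask = m.gene_ids.isin(keep)
    n_absent = len(keep) - int(mask.sum())
    if not mask.any():
        raise CountDataError("no requested gene IDs present in the matrix")
    return CountMatrix(m.counts.loc[mask]), n_absent
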