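"""Combining two routes' DEG calls into a high-confidence set.

The combining rule: genes called by *both* routes (UQ-pgQ2 + Wald and
median-of-ratios + Wald) at the shared FDR and their base cutoffs are
taken as true positives; a gene called by only one route is kept only if
that route's own |log2FC| estimate reaches the route's *max* cutoff (the
cutoff at which the mock-comparison FPR is ~ 0).  Per-gene provenance
(common / uq_only / deseq_only) is recorded, and the three classes
partition the combined set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detest import DEGCall

__all__ = [
    "CombinedDEGSet",
    "SubtypeComparison",
    "combine_true_degs",
    "compare_subtype_sets",
    "summarize_direction",
    "biomarker_report",
]


@dataclass
class CombinedDEGSet:
    """High-confidence DEG set with per-gene provenance and statistics.

    ``table`` columns: provenance (common/uq_only/deseq_only), log2fc_uq,
    padj_uq, log2fc_deseq, padj_deseq.
    """

    table: pd.DataFrame
    fdr: float
    max_cutoff_uq: float
    max_cutoff_deseq: float

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def provenance_counts(self) -> dict[str, int]:
        c = self.table["provenance"].value_counts()
        return {k: int(c.get(k, 0)) for k in ("common", "uq_only", "deseq_only")}

    def __len__(self) -> int:
        return len(self.table)

    def _check_invariants(self) -> None:
        counts = self.provenance_counts()
        assert sum(counts.values()) == len(self.table)
        uq_only = self.table[self.table["provenance"] == "uq_only"]
        assert (uq_only["log2fc_uq"].abs() >= self.max_cutoff_uq).all()
        ds_only = self.table[self.table["provenance"] == "deseq_only"]
        assert (ds_only["log2fc_deseq"].abs() >= self.max_cutoff_deseq).all()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def combine_true_degs(
    res_uq: pd.DataFrame,
    call_uq: DEGCall,
    res_deseq: pd.DataFrame,
    call_deseq: DEGCall,
    max_cutoff_uq: float,
    max_cutoff_deseq: float,
) -> CombinedDEGSet:
    """Apply the combining rule to the two routes' results and calls.

    ``res_uq``/``res_deseq`` are full per-gene test tables over the same
    gene universe; ``call_uq``/``call_deseq`` their DEG calls at a common
    FDR.  Method-unique genes are retained when the calling method's own
    |log2fc| is at or above that method's max cutoff (inclusive).
    """
    if call_uq.fdr != call_deseq.fdr:
        raise ValueError(
            f"calls made at different FDR thresholds: {call_uq.fdr} vs {call_deseq.fdr}"
        )
    if max_cutoff_uq < call_uq.lfc_cutoff or max_cutoff_deseq < call_deseq.lfc_cutoff:
        raise ValueError("max cutoffs must be at or above the base cutoffs")
    if len(res_uq.index) != len(res_deseq.index) or set(res_uq.index) != set(res_deseq.index):
        raise ValueError(
            "gene universes differ between routes: "
            f"{len(res_uq.index)} vs {len(res_deseq.index)} genes, "
            f"{len(set(res_uq.index) ^ set(res_deseq.index))} in symmetric difference"
        )

    set_uq = set(call_uq.genes)
    set_ds = set(call_deseq.genes)
    common = set_uq & set_ds
    uq_only = {
        g for g in set_uq - set_ds
        if abs(res_uq.at[g, "log2fc"]) >= max_cutoff_uq
    }
    ds_only = {
        g for g in set_ds - set_uq
        if abs(res_deseq.at[g, "log2fc"]) >= max_cutoff_deseq
    }

    genes, provenance = [], []
    for cls, members in (("common", common), ("uq_only", uq_only),
                         ("deseq_only", ds_only)):
        ordered = [g for g in res_uq.index if g in members]
        genes.extend(ordered)
        provenance.extend([cls] * len(ordered))
    idx = pd.Index(genes, name="gene_id")
    table = pd.DataFrame(
        {
            "provenance": provenance,
            "log2fc_uq": res_uq.loc[idx, "log2fc"].to_numpy(),
            "padj_uq": res_uq.loc[idx, "padj"].to_numpy(),
            "log2fc_deseq": res_deseq.loc[idx, "log2fc"].to_numpy(),
            "padj_deseq": res_deseq.loc[idx, "padj"].to_numpy(),
        },
        index=idx,
    )
    out = CombinedDEGSet(
        table=table,
        fdr=call_uq.fdr,
        max_cutoff_uq=float(max_cutoff_uq),
        max_cutoff_deseq=float(max_cutoff_deseq),
    )
    out._check_invariants()
    return out


@dataclass(frozen=True)
class SubtypeComparison:
    """Common and unique genes between two combined DEG sets."""

    common: frozenset
    unique_a: frozenset
    unique_b: frozenset
    direction_counts: dict

    @property
    def n_common(self) -> int:
        return len(self.common)

    @property
    def n_unique_a(self) -> int:
        return len(self.unique_a)

    @property
    def n_unique_b(self) -> int:
        return len(self.unique_b)


def compare_subtype_sets(a: CombinedDEGSet, b: CombinedDEGSet) -> SubtypeComparison:
    """Set decomposition of two subtypes' combined DEG sets.

    The common set and the two unique sets partition the union; up/down
    counts use each input set's own UQ-route log2fc (falling back to the
    other route's estimate for genes that route did not call).
    """
    sa, sb = set(a.genes), set(b.genes)
    common = sa & sb

    def updown(cs: CombinedDEGSet, members: set) -> tuple[int, int]:
        t = cs.table.loc[[g for g in cs.genes if g in members]]
        lfc = t["log2fc_uq"].where(~t["log2fc_uq"].isna(), t["log2fc_deseq"])
        return int((lfc > 0).sum()), int((lfc < 0).sum())

    return SubtypeComparison(
        common=frozenset(common),
        unique_a=frozenset(sa - sb),
        unique_b=frozenset(sb - sa),
        direction_counts={
            "common": updown(a, common),
            "unique_a": updown(a, sa - sb),
            "unique_b": updown(b, sb - sa),
        },
    )


def summarize_direction(log2fc: pd.Series) -> tuple[int, int]:
    """Up/down counts for a called gene set; zero log2fc is a contract error."""
    vals = log2fc.to_numpy(dtype=float)
    if np.any(vals == 0):
        zeros = list(log2fc.index[vals == 0][:5])
        raise ValueError(f"called genes with log2fc == 0: {zeros}")
    return int((vals > 0).sum()), int((vals < 0).sum())


def biomarker_report(
    res_uq: pd.DataFrame,
    res_deseq: pd.DataFrame,
    call_uq: DEGCall,
    call_deseq: DEGCall,
    genes,
) -> pd.DataFrame:
    """Per-gene lookup table across both routes for marker genes.

    One row per requested gene with log2fc/padj from each route and
    whether each route called it; genes absent from the tested universe
    are kept and flagged rather than dropped.
    """
    columns = ["present", "log2fc_uq", "padj_uq", "called_uq",
               "log2fc_deseq", "padj_deseq", "called_deseq"]
    rows = []
    uq_called, ds_called = set(call_uq.genes), set(call_deseq.genes)
    for g in genes:
        present = g in res_uq.index
        rows.append(
            {
                "gene_id": g,
                "present": present,
                "log2fc_uq": res_uq.at[g, "log2fc"] if present else np.nan,
                "padj_uq": res_uq.at[g, "padj"] if present else np.nan,
                "called_uq": g in uq_called,
                "log2fc_deseq": res_deseq.at[g, "log2fc"] if present else np.nan,
                "padj_deseq": res_deseq.at[g, "padj"] if present else np.nan,
                "called_deseq": g in ds_called,
            }
        )
    if not rows:
        return pd.DataFrame(columns=columns, index=pd.Index([], name="gene_id"))
    return pd.DataFrame(rows).set_index("gene_id")
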