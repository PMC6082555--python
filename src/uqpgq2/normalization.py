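"""Count normalization: two-stage UQ-pgQ2 and median-of-ratios size factors.

UQ-pgQ2 first scales each sample by its upper quartile (75th percentile of
counts over genes), then scales each gene by its across-sample median of
the stage-1 values, times a constant (default 100) that keeps values
count-like.  Per-gene median scaling equalizes the within-gene scale across
the dynamic range, which is what damps false positives among very
high-count genes (residual rRNA and other contaminants).

Median-of-ratios is the classical DESeq size-factor estimator: per sample,
the median over genes of the ratio of the sample's count to the gene's
geometric-mean reference, rescaled here to geometric mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .countdata import CountMatrix

__all__ = [
    "NormalizationError",
    "NormalizedMatrix",
    "upper_quartile_factors",
    "uq_pgq2_normalize",
    "median_of_ratios_factors",
]


class NormalizationError(ValueError):
    """Normalization cannot be computed for this matrix."""


@dataclass(frozen=True)
class NormalizedMatrix:
    """Normalized expression values with the factors that produced them.

    values = raw * gene_factor[g] * (1 / sample_factor[j]) * scale_constant.
    For ``uq_pgq2`` the sample factor is the upper quartile and the gene
    factor 1/Q2; for ``deseq_mor`` the gene factors are all 1 and the
    scale constant 1.  ``flagged_genes`` had an all-zero across-sample
    median at stage 1 and used the smallest positive stage-1 value instead
    (or were left at zero if the gene is zero everywhere).
    """

    values: pd.DataFrame
    method: str
    sample_factors: pd.Series
    gene_factors: pd.Series
    scale_constant: float
    flagged_genes: pd.Index

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def rounded_counts(self) -> pd.DataFrame:
        """Values rounded half-to-even to integers, for count-model testing."""
        return pd.DataFrame(
            np.rint(self.values.to_numpy()).astype(np.int64),
            index=self.values.index,
            columns=self.values.columns,
        )

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    def factors_to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# kind\tid\tfactor\n")
            for sid, f in self.sample_factors.items():
                fh.write(f"sample\t{sid}\t{f:.10g}\n")
            for gid, f in self.gene_factors.items():
                fh.write(f"gene\t{gid}\t{f:.10g}\n")


def upper_quartile_factors(m: CountMatrix, positive_only: bool = False) -> pd.Series:
    """Per-sample 75th percentile of counts over genes (linear interpolation).

    By default the quantile is taken over all genes in the (already
    zero-filtered) matrix, including genes that happen to be zero in that
    particular sample; ``positive_only`` restricts to the sample's positive
    counts instead.
    """
    uq = {}
    for j, sid in enumerate(m.sample_ids):
        col = m.values[:, j]
        if positive_only:
            col = col[col > 0]
        if col.size == 0 or (q := float(np.percentile(col, 75))) == 0.0:
            raise NormalizationError(
                f"upper quartile is zero for sample {sid!r}; "
                "data too sparse for upper-quartile scaling"
            )
        uq[sid] = q
    return pd.Series(uq, name="upper_quartile")


def uq_pgq2_normalize(
    m: CountMatrix,
    scale_constant: float = 100.0,
    uq_positive_only: bool = False,
) -> NormalizedMatrix:
    """Two-stage UQ-pgQ2 normalization.

    Stage 1 divides each sample by its upper quartile; stage 2 divides each
    gene by its across-sample median of stage-1 values (Q2) and multiplies
    by ``scale_constant``, so every gene with a positive Q2 has a
    post-normalization median exactly equal to the constant.  Genes with
    Q2 = 0 fall back to their smallest positive stage-1 value and are
    flagged; genes that are zero everywhere keep a unit gene factor.
    """
    if scale_constant <= 0:
        raise NormalizationError("scale_constant must be positive")
    uq = upper_quartile_factors(m, positive_only=uq_positive_only)
    stage1 = m.values / uq.to_numpy()[None, :]
    q2 = np.median(stage1, axis=1)
    flagged = q2 == 0.0
    q2_eff = q2.copy()
    for g in np.nonzero(flagged)[0]:
        pos = stage1[g][stage1[g] > 0]
        q2_eff[g] = pos.min() if pos.size else 1.0
    values = scale_constant * stage1 / q2_eff[:, None]
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=m.gene_ids, columns=m.sample_ids),
        method="uq_pgq2",
        sample_factors=uq,
        gene_factors=pd.Series(1.0 / q2_eff, index=m.gene_ids, name="inv_q2"),
        scale_constant=float(scale_constant),
        flagged_genes=m.gene_ids[flagged],
    )


def median_of_ratios_factors(m: CountMatrix) -> pd.Series:
    """DESeq-style median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-gene geometric mean over samples, taken over
    genes with strictly positive counts in every sample; each sample's
    factor is the median ratio of its counts to the reference.
    """
    x = m.values.astype(float)
    all_pos = (x > 0).all(axis=1)
    if not all_pos.any():
        raise NormalizationError(
            "no gene has positive counts in every sample; "
            "median-of-ratios reference undefined"
        )
    logs = np.log(x[all_pos])
    log_ref = logs.mean(axis=1)
    log_ratios = logs - log_ref[:, None]
    log_s = np.median(log_ratios, axis=0)
    log_s -= log_s.mean()  # geometric mean 1
    return pd.Series(np.exp(log_s), index=m.sample_ids, name="size_factor")
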