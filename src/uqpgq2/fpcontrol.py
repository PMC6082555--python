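"""Within-group mock comparisons for empirical false-positive control.

Samples from a single biological condition are split at random into two
equal halves and the full differential-expression route is run on the
split; because both halves come from the same condition, every call is a
false positive by construction.  Repeating the split (default 10 times)
and counting calls across a grid of |log2FC| cutoffs yields an empirical
false-positive rate (FPR, in percent of genes tested) per cutoff, from
which two cutoffs are selected: the *base* cutoff (smallest cutoff with
FPR <= 0.05%) used for ordinary DEG calling, and the *max* cutoff
(smallest cutoff with FPR ~ 0) used to admit method-unique genes into the
combined true-DEG set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .countdata import CountMatrix
from .detest import run_de_route

__all__ = [
    "SplitPlan",
    "FPRReport",
    "CutoffSelection",
    "random_equal_split",
    "within_group_fpr",
    "select_base_cutoff",
    "select_max_cutoff",
]

DEFAULT_GRID = (1.0, 1.5, 2.0, 2.5, 3.0)


@dataclass(frozen=True)
class SplitPlan:
    """One random equal partition of same-condition samples."""

    repetition: int
    half_a: tuple
    half_b: tuple

    def __post_init__(self):
        a, b = set(self.half_a), set(self.half_b)
        if a & b:
            raise ValueError("split halves overlap")
        if abs(len(a) - len(b)) > 1:
            raise ValueError("split halves differ in size by more than 1")


def random_equal_split(sample_ids, seed: int, repetition: int = 1) -> SplitPlan:
    """Uniform random partition into halves of size ceil(n/2) and floor(n/2).

    Deterministic given ``seed``; requires at least 4 samples so each half
    has the two replicates the NB test needs.
    """
    ids = list(sample_ids)
    n = len(ids)
    if n < 4:
        raise ValueError(f"need at least 4 samples to split, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    k = (n + 1) // 2
    return SplitPlan(
        repetition=repetition,
        half_a=tuple(ids[i] for i in perm[:k]),
        half_b=tuple(ids[i] for i in perm[k:]),
    )


@dataclass
class FPRReport:
    """False-positive counts and rates across a |log2FC| cutoff grid.

    ``table`` has one row per cutoff with mean_fp, sd_fp and fpr_percent
    (= 100 * mean_fp / n_genes); ``per_repetition`` holds the raw counts,
    one row per repetition; ``seeds`` the derived per-repetition seeds.
    """

    route: str
    n_genes: int
    n_repeats: int
    fdr: float
    seed: int
    grid: tuple
    table: pd.DataFrame
    per_repetition: pd.DataFrame
    seeds: tuple


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive per-repetition seeds from a master seed (counter scheme)."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def within_group_fpr(
    m: CountMatrix,
    sample_ids,
    route: str,
    grid=DEFAULT_GRID,
    n_repeats: int = 10,
    fdr: float = 0.05,
    seed: int = 0,
    scale_constant: float = 100.0,
) -> FPRReport:
    """Repeated random-split mock comparison on one condition's samples.

    Each repetition partitions ``sample_ids`` into two halves, runs the
    full route (normalize, NB Wald test, BH adjustment) and counts genes
    with padj <= fdr and |log2fc| >= c for every grid cutoff c.
    """
    grid = tuple(sorted(float(c) for c in grid))
    if not grid:
        raise ValueError("cutoff grid is empty")
    sub = m.select_samples(list(sample_ids))
    seeds = _spawn_seeds(seed, n_repeats)
    counts = np.zeros((n_repeats, len(grid)), dtype=int)
    for rep in range(n_repeats):
        plan = random_equal_split(sub.sample_ids, seeds[rep], repetition=rep + 1)
        groups = pd.Series(
            {**{s: "half_a" for s in plan.half_a},
             **{s: "half_b" for s in plan.half_b}}
        )
        try:
            res = run_de_route(sub, groups, "half_a", "half_b", route,
                               scale_constant=scale_constant)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(
                f"repetition {rep + 1} (seed {seeds[rep]}) failed: {exc}"
            ) from exc
        padj = res.table["padj"].to_numpy()
        lfc = np.abs(res.table["log2fc"].to_numpy())
        sig = (~np.isnan(padj)) & (padj <= fdr)
        for j, c in enumerate(grid):
            counts[rep, j] = int((sig & (lfc >= c)).sum())

    mean_fp = counts.mean(axis=0)
    sd_fp = counts.std(axis=0, ddof=1) if n_repeats > 1 else np.zeros(len(grid))
    table = pd.DataFrame(
        {
            "cutoff": grid,
            "mean_fp": mean_fp,
            "sd_fp": sd_fp,
            "fpr_percent": 100.0 * mean_fp / sub.n_genes,
        }
    ).set_index("cutoff")
    per_rep = pd.DataFrame(
        counts, columns=list(grid),
        index=pd.RangeIndex(1, n_repeats + 1, name="repetition"),
    )
    return FPRReport(
        route=route,
        n_genes=sub.n_genes,
        n_repeats=n_repeats,
        fdr=fdr,
        seed=seed,
        grid=grid,
        table=table,
        per_repetition=per_rep,
        seeds=tuple(seeds),
    )


@dataclass(frozen=True)
class CutoffSelection:
    """Cutoffs chosen from an FPR report; None marks "no cutoff qualifies"."""

    base_cutoff: float | None = None
    max_cutoff: float | None = None
    fpr_threshold_percent: float | None = None
    epsilon_percent: float | None = None

    def merged(self, other: "CutoffSelection") -> "CutoffSelection":
        sel = CutoffSelection(
            base_cutoff=self.base_cutoff if self.base_cutoff is not None else other.base_cutoff,
            max_cutoff=self.max_cutoff if self.max_cutoff is not None else other.max_cutoff,
            fpr_threshold_percent=self.fpr_threshold_percent
            if self.fpr_threshold_percent is not None else other.fpr_threshold_percent,
            epsilon_percent=self.epsilon_percent
            if self.epsilon_percent is not None else other.epsilon_percent,
        )
        if (sel.base_cutoff is not None and sel.max_cutoff is not None
                and sel.max_cutoff < sel.base_cutoff):
            raise ValueError("max cutoff smaller than base cutoff")
        return sel


def _smallest_qualifying(report: FPRReport, threshold_percent: float) -> float | None:
    for c in report.grid:
        if report.table.loc[c, "fpr_percent"] <= threshold_percent:
            return float(c)
    return None


def select_base_cutoff(report: FPRReport,
                       fpr_threshold_percent: float = 0.05) -> CutoffSelection:
    """Smallest grid cutoff whose FPR is at or below the threshold (0.05%)."""
    return CutoffSelection(
        base_cutoff=_smallest_qualifying(report, fpr_threshold_percent),
        fpr_threshold_percent=fpr_threshold_percent,
    )


def select_max_cutoff(report: FPRReport,
                      epsilon_percent: float = 0.005) -> CutoffSelection:
    """Smallest grid cutoff with FPR ~ 0 (at or below epsilon percent)."""
    return CutoffSelection(
        max_cutoff=_smallest_qualifying(report, epsilon_percent),
        epsilon_percent=epsilon_percent,
    )
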