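"""End-to-end orchestration: within-group cutoff selection, between-group
combined DEG calling, and run manifests for auditability."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field

import pandas as pd

from .countdata import CountMatrix
from .degsets import CombinedDEGSet, combine_true_degs
from .detest import NBWaldDEResults, call_degs, run_de_route
from .fpcontrol import (
    DEFAULT_GRID,
    CutoffSelection,
    FPRReport,
    select_base_cutoff,
    select_max_cutoff,
    within_group_fpr,
)

__all__ = ["RunManifest", "run_within_group", "run_between_group"]


@dataclass
class RunManifest:
    """Audit record of one pipeline run: inputs, parameters, seeds, timing."""

    stage: str
    parameters: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    seconds: float = 0.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def checksum_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_within_group(
    m: CountMatrix,
    sheet: pd.DataFrame,
    group: str,
    route: str,
    grid=DEFAULT_GRID,
    n_repeats: int = 10,
    fdr: float = 0.05,
    seed: int = 0,
    fpr_threshold_percent: float = 0.05,
    epsilon_percent: float = 0.005,
    scale_constant: float = 100.0,
) -> tuple[FPRReport, CutoffSelection, RunManifest]:
    """Mock-comparison stage: split one condition, measure FPR, pick cutoffs."""
    t0 = time.perf_counter()
    ids = sheet.loc[sheet["group"] == group, "sample_id"].tolist()
    if len(ids) < 4:
        raise ValueError(f"group {group!r} has {len(ids)} samples; need >= 4")
    report = within_group_fpr(
        m, ids, route, grid=grid, n_repeats=n_repeats, fdr=fdr, seed=seed,
        scale_constant=scale_constant,
    )
    selection = select_base_cutoff(report, fpr_threshold_percent).merged(
        select_max_cutoff(report, epsilon_percent)
    )
    manifest = RunManifest(
        stage="within_group",
        parameters={
            "group": group, "route": route, "grid": list(report.grid),
            "n_repeats": n_repeats, "fdr": fdr, "seed": seed,
            "fpr_threshold_percent": fpr_threshold_percent,
            "epsilon_percent": epsilon_percent,
        },
        inputs={"n_genes": report.n_genes, "n_samples": len(ids)},
        outputs={
            "base_cutoff": selection.base_cutoff,
            "max_cutoff": selection.max_cutoff,
            "per_repetition_seeds": list(report.seeds),
        },
        seconds=time.perf_counter() - t0,
    )
    return report, selection, manifest


def run_between_group(
    m: CountMatrix,
    sheet: pd.DataFrame,
    test_group: str,
    ref_group: str,
    base_cutoff_uq: float,
    base_cutoff_deseq: float,
    max_cutoff_uq: float,
    max_cutoff_deseq: float,
    fdr: float = 0.05,
    scale_constant: float = 100.0,
) -> tuple[CombinedDEGSet, NBWaldDEResults, NBWaldDEResults, RunManifest]:
    """Between-group stage: run both routes, call DEGs, combine.

    Both routes are fitted at the shared FDR and their own base cutoffs;
    method-unique genes must clear that method's max cutoff to enter the
    combined set.
    """
    t0 = time.perf_counter()
    groups = sheet.set_index("sample_id")["group"]
    res_uq = run_de_route(m, groups, test_group, ref_group, "uq-pgq2",
                          scale_constant=scale_constant)
    res_ds = run_de_route(m, groups, test_group, ref_group, "deseq-mor")
    call_uq = call_degs(res_uq.table, fdr=fdr, lfc_cutoff=base_cutoff_uq)
    call_ds = call_degs(res_ds.table, fdr=fdr, lfc_cutoff=base_cutoff_deseq)
    combined = combine_true_degs(
        res_uq.table, call_uq, res_ds.table, call_ds,
        max_cutoff_uq, max_cutoff_deseq,
    )
    manifest = RunManifest(
        stage="between_group",
        parameters={
            "test_group": test_group, "ref_group": ref_group, "fdr": fdr,
            "base_cutoff_uq": base_cutoff_uq,
            "base_cutoff_deseq": base_cutoff_deseq,
            "max_cutoff_uq": max_cutoff_uq,
            "max_cutoff_deseq": max_cutoff_deseq,
        },
        inputs={"n_genes": m.n_genes, "n_samples": m.n_samples},
        outputs={
            "n_called_uq": len(call_uq),
            "n_called_deseq": len(call_ds),
            "combined": combined.provenance_counts() | {"total": len(combined)},
        },
        seconds=time.perf_counter() - t0,
    )
    return combined, res_uq, res_ds, manifest
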