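import numpy as np
import pandas as pd
import pytest

import uqpgq2 as u

FIXTURE_DIR = __file__.rsplit("/", 1)[0] + "/data"


def two_level_groups(sample_ids, label_a="A", label_b="B"):
    """Map the simulator's *_g1/*_g2 sample names to two condition labels."""
    return pd.Series(
        {s: (label_a if s.endswith("_g1") else label_b) for s in sample_ids}
    )


@pytest.fixture(scope="session")
def wald_fixture():
    m = u.read_count_matrix(f"{FIXTURE_DIR}/wald_fixture.tsv")
    groups = pd.Series(
        {s: ("test" if s.startswith("t") else "ref") for s in m.sample_ids}
    )
    return m, groups


@pytest.fixture(scope="session")
def null_matrix_42():
    """Null NB dataset at study scale: 20,000 genes, 42 samples of one
    condition, log-normal means, dispersion trend, unequal library sizes."""
    cfg = u.SimulationConfig(
        n_genes=20000, n1=42, n2=0,
        meanlog=4.0, sdlog=2.0,
        trend_a0=0.05, trend_a1=5.0,
        size_factor_range=(0.5, 2.0),
        de_fraction=0.0, skew_fraction=0.01,
        seed=20260901,
    )
    m, _ = u.simulate_counts(cfg)
    m, _ = u.filter_all_zero_genes(m)
    return m


@pytest.fixture(scope="session")
def null_fpr_report(null_matrix_42):
    """Within-group mock comparison on the null dataset, UQ-pgQ2 route,
    10 repetitions at FDR 0.05 over the standard cutoff grid."""
    return u.within_group_fpr(
        null_matrix_42, list(null_matrix_42.sample_ids), "uq-pgq2",
        grid=(1.0, 1.5, 2.0, 2.5, 3.0), n_repeats=10, fdr=0.05, seed=42,
    )


@pytest.fixture(scope="session")
def spiked_run():
    """End-to-end run on data with 300 spiked |log2FC|=3 genes, 21 vs 21."""
    cfg = u.SimulationConfig(
        n_genes=10000, n1=21, n2=21, alpha=0.1,
        de_fraction=0.03, lfc_magnitudes=(3.0,), skew_fraction=0.0,
        seed=777,
    )
    m, truth = u.simulate_counts(cfg)
    m, _ = u.filter_all_zero_genes(m)
    truth = truth.loc[m.gene_ids]
    sheet = pd.DataFrame(
        {
            "sample_id": list(m.sample_ids),
            "group": ["ctrl"] * 21 + ["tumor"] * 21,
        }
    )
    combined, res_uq, res_ds, manifest = u.run_between_group(
        m, sheet, "tumor", "ctrl",
        base_cutoff_uq=2.0, base_cutoff_deseq=2.0,
        max_cutoff_uq=2.0, max_cutoff_deseq=2.5,
        fdr=0.05,
    )
    return combined, res_uq, res_ds, truth
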