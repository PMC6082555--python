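import numpy as np
import pandas as pd
import pytest

import uqpgq2 as u
from uqpgq2.degsets import (
    biomarker_report,
    combine_true_degs,
    compare_subtype_sets,
    summarize_direction,
)
from uqpgq2.detest import call_degs


def build_call_tables(n_common, n_uq_only, n_deseq_only, lfc_uq_only,
                      lfc_deseq_only, n_null=500, fdr=0.05):
    """Construct a shared gene universe and two routes' result tables with
    disjoint common/unique call components of the requested sizes."""
    n = n_common + n_uq_only + n_deseq_only + n_null
    genes = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")
    common = genes[:n_common]
    uq_only = genes[n_common:n_common + n_uq_only]
    ds_only = genes[n_common + n_uq_only:n_common + n_uq_only + n_deseq_only]

    def table(called, called_lfc):
        padj = pd.Series(1.0, index=genes)
        lfc = pd.Series(0.0, index=genes)
        padj[called] = 0.001
        lfc[called] = called_lfc
        return pd.DataFrame({"padj": padj, "log2fc": lfc, "pvalue": padj})

    res_uq = table(common, 3.0)
    res_uq.loc[uq_only, ["padj", "log2fc"]] = [0.001, lfc_uq_only]
    res_ds = table(common, 3.0)
    res_ds.loc[ds_only, ["padj", "log2fc"]] = [0.001, lfc_deseq_only]
    call_uq = call_degs(res_uq, fdr=fdr, lfc_cutoff=2.0)
    call_ds = call_degs(res_ds, fdr=fdr, lfc_cutoff=2.0)
    return res_uq, call_uq, res_ds, call_ds


class TestCombineTrueDegs:
    def test_tnbc_sized_components_total(self):
        """Common 1546 + 38 UQ-only at |logFC|>=2 + 109 route-B-only at
        |logFC|>=2.5 combine to 1693 genes."""
        res_uq, call_uq, res_ds, call_ds = build_call_tables(
            1546, 38, 109, lfc_uq_only=2.0, lfc_deseq_only=2.5
        )
        combined = combine_true_degs(res_uq, call_uq, res_ds, call_ds,
                                     max_cutoff_uq=2.0, max_cutoff_deseq=2.5)
        assert len(combined) == 1693
        assert combined.provenance_counts() == {
            "common": 1546, "uq_only": 38, "deseq_only": 109
        }

    def test_er_sized_components_total(self):
        """Common 2212 + 3 + 84 with both max cutoffs at 2 gives 2299."""
        res_uq, call_uq, res_ds, call_ds = build_call_tables(
            2212, 3, 84, lfc_uq_only=2.0, lfc_deseq_only=2.0
        )
        combined = combine_true_degs(res_uq, call_uq, res_ds, call_ds,
                                     max_cutoff_uq=2.0, max_cutoff_deseq=2.0)
        assert len(combined) == 2299

    def test_unique_below_max_cutoff_dropped(self):
        res_uq, call_uq, res_ds, call_ds = build_call_tables(
            0, 5, 7, lfc_uq_only=2.0, lfc_deseq_only=2.0
        )
        combined = combine_true_degs(res_uq, call_uq, res_ds, call_ds,
                                     max_cutoff_uq=2.5, max_cutoff_deseq=2.5)
        assert len(combined) == 0

    def test_subset_of_union_superset_of_intersection(self):
        res_uq, call_uq, res_ds, call_ds = build_call_tables(
            10, 6, 4, lfc_uq_only=2.0, lfc_deseq_only=3.0
        )
        combined = combine_true_degs(res_uq, call_uq, res_ds, call_ds, 2.5, 2.5)
        union = set(call_uq.genes) | set(call_ds.genes)
        inter = set(call_uq.genes) & set(call_ds.genes)
        got = set(combined.genes)
        assert inter <= got <= union

    def test_mismatched_universes_rejected(self):
        res_uq, call_uq, res_ds, call_ds = build_call_tables(3, 1, 1, 2.0, 2.0)
        with pytest.raises(ValueError, match="universes"):
            combine_true_degs(res_uq.iloc[:-1], call_uq, res_ds, call_ds, 2, 2)

    def test_different_fdr_rejected(self):
        res_uq, call_uq, res_ds, _ = build_call_tables(3, 1, 1, 2.0, 2.0)
        call_ds_other = call_degs(res_ds, fdr=0.1, lfc_cutoff=2.0)
        with pytest.raises(ValueError, match="FDR"):
            combine_true_degs(res_uq, call_uq, res_ds, call_ds_other, 2, 2)

    def test_max_below_base_rejected(self):
        res_uq, call_uq, res_ds, call_ds = build_call_tables(3, 1, 1, 2.0, 2.0)
        with pytest.raises(ValueError, match="max cutoffs"):
            combine_true_degs(res_uq, call_uq, res_ds, call_ds, 1.0, 2.0)


class TestCompareSubtypeSets:
    def combined_from(self, gene_ids, lfc=2.5):
        idx = pd.Index(gene_ids, name="gene_id")
        table = pd.DataFrame(
            {"provenance": "common", "log2fc_uq": lfc, "padj_uq": 0.001,
             "log2fc_deseq": lfc, "padj_deseq": 0.001},
            index=idx,
        )
        return u.CombinedDEGSet(table=table, fdr=0.05, max_cutoff_uq=2.0,
                                max_cutoff_deseq=2.0)

    def test_set_algebra(self):
        cmp_ = compare_subtype_sets(
            self.combined_from(["a", "b", "c"]), self.combined_from(["b", "c", "d"])
        )
        assert cmp_.common == {"b", "c"}
        assert cmp_.unique_a == {"a"} and cmp_.unique_b == {"d"}

    def test_partition_cardinalities(self):
        a = self.combined_from([f"g{i}" for i in range(1693)])
        b_genes = [f"g{i}" for i in range(896)] + [f"h{i}" for i in range(1403)]
        b = self.combined_from(b_genes)
        cmp_ = compare_subtype_sets(a, b)
        assert cmp_.n_common == 896
        assert cmp_.n_unique_a == 1693 - 896 == 797
        assert cmp_.n_unique_b == 2299 - 896 == 1403
        assert cmp_.n_common + cmp_.n_unique_a + cmp_.n_unique_b == len(
            set(a.genes) | set(b.genes)
        )

    def test_symmetry(self):
        a = self.combined_from(["a", "b"])
        b = self.combined_from(["b", "c"])
        fwd = compare_subtype_sets(a, b)
        rev = compare_subtype_sets(b, a)
        assert fwd.common == rev.common
        assert fwd.unique_a == rev.unique_b and fwd.unique_b == rev.unique_a

    def test_identical_sets(self):
        a = self.combined_from(["x", "y"])
        cmp_ = compare_subtype_sets(a, self.combined_from(["x", "y"]))
        assert not cmp_.unique_a and not cmp_.unique_b


class TestSummarizeDirection:
    def test_counts(self):
        s = pd.Series([2.1, -3.0, 4.0], index=["a", "b", "c"])
        assert summarize_direction(s) == (2, 1)

    def test_empty(self):
        assert summarize_direction(pd.Series(dtype=float)) == (0, 0)

    def test_zero_lfc_rejected(self):
        with pytest.raises(ValueError, match="log2fc == 0"):
            summarize_direction(pd.Series([1.0, 0.0], index=["a", "b"]))

    def test_conservation_on_pipeline_output(self, spiked_run):
        combined, _, _, _ = spiked_run
        up, down = summarize_direction(combined.table["log2fc_uq"])
        assert up + down == len(combined)


class TestBiomarkerReport:
    def test_absent_gene_flagged_not_dropped(self):
        res_uq, call_uq, res_ds, call_ds = build_call_tables(3, 0, 0, 2.0, 2.0)
        rep = biomarker_report(res_uq, res_ds, call_uq, call_ds,
                               ["g00000", "ESR1"])
        assert len(rep) == 2
        assert bool(rep.at["g00000", "present"])
        assert not bool(rep.at["ESR1", "present"])
        assert np.isnan(rep.at["ESR1", "log2fc_uq"])

    def test_empty_request(self):
        res_uq, call_uq, res_ds, call_ds = build_call_tables(2, 0, 0, 2.0, 2.0)
        assert len(biomarker_report(res_uq, res_ds, call_uq, call_ds, [])) == 0

    def test_spiked_down_gene_negative_in_both_routes(self, spiked_run):
        combined, res_uq, res_ds, truth = spiked_run
        down = truth.index[truth["true_log2fc"] < 0][:5]
        call_uq = u.call_degs(res_uq.table, 0.05, 2.0)
        call_ds = u.call_degs(res_ds.table, 0.05, 2.0)
        rep = biomarker_report(res_uq.table, res_ds.table, call_uq, call_ds, down)
        assert (rep["log2fc_uq"] < 0).all() and (rep["log2fc_deseq"] < 0).all()
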