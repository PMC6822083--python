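"""Tests of DNA-vs-RNA concordance classification and cohort summaries."""

import pytest
from hypothesis import given, strategies as st

from panoutlier.concordance import (
    ConcordanceRecord,
    MutationFinding,
    classify_sample,
    expression_support_check,
    percentage,
    summarize_cohort,
    venn_table,
)
from panoutlier.druggability import ActionableFinding
from panoutlier.errors import InputError


def dna(gene, sample_id="S1", actionable=True, allele=None, downstream=()):
    return MutationFinding(
        sample_id=sample_id,
        gene=gene,
        variant="variant",
        variant_class="SNV",
        dna_actionable=actionable,
        rna_mutant_allele_expressed=allele,
        downstream_pathway_groups=frozenset(downstream),
    )


def rna(symbol, sample_id="S1", group="RTK"):
    return ActionableFinding(sample_id, symbol, "direct", group, frozenset({"pan_cancer"}))


class TestExpressionSupportCheck:
    def test_mutated_gene_itself_an_outlier(self):
        assert expression_support_check("FLT3", ["FLT3", "BTK"], []) == "gene_level"

    def test_ras_downstream_pathways_enriched(self):
        level = expression_support_check(
            "NRAS",
            outlier_genes=[],
            enriched_groups=["cell-cycle", "BCL2-MDM2"],
            downstream_groups=["RAS-RAF-MEK", "cell-cycle", "BCL2-MDM2"],
        )
        assert level == "downstream"

    def test_no_outlier_no_enrichment_is_none(self):
        assert expression_support_check("NRAS", [], [], ["RAS-RAF-MEK"]) == "none"


class TestClassifySample:
    def test_unexpressed_mutation_without_support_deprioritized(self):
        # a point mutation absent from the RNA, with no downstream signal
        record = classify_sample(
            "S1", [dna("BRAF", allele=False)], rna=[rna("CDK6", group="cell-cycle")]
        )
        assert record.venn_cell == "both"
        assert record.utility_mode == "deprioritize"

    def test_fusion_with_downstream_enrichment_supported(self):
        record = classify_sample(
            "S1",
            [dna("BCR-ABL1", downstream=("PI3K-AKT-mTOR", "BCR"))],
            rna=[rna("CDK6", group="cell-cycle")],
            enriched_groups=["PI3K-AKT-mTOR"],
        )
        assert record.venn_cell == "both"
        assert record.utility_mode == "support"

    def test_no_findings_at_all(self):
        record = classify_sample("S1", [], [])
        assert record.venn_cell == "neither"
        assert record.utility_mode == "none"

    def test_multiple_dna_genes_with_support_prioritized(self):
        findings = [
            dna("NRAS", downstream=("cell-cycle",)),
            dna("KRAS", downstream=("RAS-RAF-MEK",)),
        ]
        record = classify_sample(
            "S1", findings, rna=[rna("FLT3")], enriched_groups=["cell-cycle"]
        )
        assert record.utility_mode == "prioritize"

    def test_rna_only_mode_iff_rna_only_cell(self):
        record = classify_sample("S1", [], [rna("FLT3")])
        assert record.venn_cell == "rna_only"
        assert record.utility_mode == "rna_only"
        # non-actionable DNA findings do not change the cell
        record = classify_sample("S1", [dna("TTN", actionable=False)], [rna("FLT3")])
        assert record.venn_cell == "rna_only"

    def test_unknown_allele_status_never_deprioritizes(self):
        record = classify_sample("S1", [dna("BRAF", allele=None)], [rna("FLT3")])
        assert record.utility_mode == "none"

    def test_mismatched_sample_ids_rejected(self):
        with pytest.raises(InputError):
            classify_sample("S1", [dna("BRAF", sample_id="S2")], [])

    def test_record_invariants_enforced(self):
        with pytest.raises(InputError):
            ConcordanceRecord("S1", True, True, "neither", "none")
        with pytest.raises(InputError):
            ConcordanceRecord("S1", False, True, "rna_only", "none")


class TestSummarizeCohort:
    def _records(self, both=0, dna_only=0, rna_only=0, neither=0):
        records = []
        cells = (
            [("both", True, True)] * both
            + [("dna_only", True, False)] * dna_only
            + [("rna_only", False, True)] * rna_only
            + [("neither", False, False)] * neither
        )
        for i, (cell, d, r) in enumerate(cells):
            mode = "rna_only" if cell == "rna_only" else "none"
            records.append(ConcordanceRecord(f"S{i}", d, r, cell, mode))
        return records

    def test_printed_partition_percentages(self):
        # the 74-sample partition 28/6/27/13 reproduces the one-decimal
        # percentages 37.8 / 8.1 / 36.5 / 17.6, with margins 34 (45.9%)
        # DNA-actionable and 55 (74.3%) RNA-actionable
        summary = summarize_cohort(self._records(both=28, dna_only=6, rna_only=27, neither=13))
        assert summary.n_total == 74
        assert summary.percentages["both"] == 37.8
        assert summary.percentages["dna_only"] == 8.1
        assert summary.percentages["rna_only"] == 36.5
        assert summary.percentages["neither"] == 17.6
        assert summary.counts["dna_actionable"] == 34
        assert summary.percentages["dna_actionable"] == 45.9
        assert summary.counts["rna_actionable"] == 55
        assert summary.percentages["rna_actionable"] == 74.3

    def test_99_of_144_is_68_8(self):
        assert percentage(99, 144) == 68.8

    def test_single_record(self):
        summary = summarize_cohort(self._records(both=1))
        assert summary.percentages["both"] == 100.0
        assert summary.percentages["neither"] == 0.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(InputError):
            summarize_cohort([])

    @given(
        counts=st.tuples(
            st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20)
        ).filter(lambda c: sum(c) > 0),
        seed=st.integers(0, 1000),
    )
    def test_partition_exhaustive_and_permutation_invariant(self, counts, seed):
        import random

        records = self._records(*counts)
        shuffled = records[:]
        random.Random(seed).shuffle(shuffled)
        a = summarize_cohort(records)
        b = summarize_cohort(shuffled)
        assert a == b
        assert sum(a.counts[c] for c in ("both", "dna_only", "rna_only", "neither")) == a.n_total

    def test_venn_table_layout(self):
        summary = summarize_cohort(self._records(both=28, dna_only=6, rna_only=27, neither=13))
        table = venn_table(summary)
        assert table[1][1] == 28 and table[1][2] == 6
        assert table[2][1] == 27 and table[2][2] == 13
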