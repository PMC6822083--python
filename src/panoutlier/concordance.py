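"""DNA versus RNA actionability concordance.

Each tumor with both DNA mutation findings and RNA outlier results is
placed in one cell of the 2x2 partition (both / DNA-only / RNA-only /
neither) and assigned a utility mode describing how the expression
evidence modifies interpretation of the DNA findings:

* ``support`` — a single actionable DNA gene is corroborated by RNA,
  either because the mutated gene is itself an expression outlier or
  because its known downstream pathway groups are enriched;
* ``prioritize`` — several actionable DNA genes, at least one with such
  RNA corroboration, so expression ranks the candidates;
* ``deprioritize`` — a DNA finding whose mutant allele is absent from the
  RNA and which has no downstream expression support;
* ``rna_only`` — actionable expression outliers with no DNA finding;
* ``none`` — anything else.

Downstream gene-to-pathway links are data (an editable curated table),
not code; a gene absent from the table simply provides no downstream
support, which is the conservative reading of ambiguous biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from .druggability import ActionableFinding
from .errors import InputError

VARIANT_CLASSES = ("SNV", "fusion", "CNV_gain", "loss")
VENN_CELLS = ("both", "dna_only", "rna_only", "neither")
UTILITY_MODES = ("support", "prioritize", "deprioritize", "rna_only", "none")


@dataclass(frozen=True)
class MutationFinding:
    """One DNA aberration reported for a sample.

    ``dna_actionable`` reflects treatment-arm style curation of the
    variant (an input, not computed here); ``rna_mutant_allele_expressed``
    comes from upstream allele counting and ``None`` means unknown, which
    is treated as expressed — a sample is never deprioritized without
    evidence. ``downstream_pathway_groups`` lists the pathway groups
    expected to be transcriptionally active if the variant is functional.
    """

    sample_id: str
    gene: str
    variant: str
    variant_class: str
    dna_actionable: bool
    rna_mutant_allele_expressed: bool | None = None
    downstream_pathway_groups: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise InputError(f"unknown variant class {self.variant_class!r}")


@dataclass(frozen=True)
class ConcordanceRecord:
    sample_id: str
    dna_flag: bool
    rna_flag: bool
    venn_cell: str
    utility_mode: str
    evidence: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        expected = _venn_cell(self.dna_flag, self.rna_flag)
        if self.venn_cell != expected:
            raise InputError(
                f"venn cell {self.venn_cell!r} inconsistent with flags "
                f"(dna={self.dna_flag}, rna={self.rna_flag})"
            )
        if (self.utility_mode == "rna_only") != (self.venn_cell == "rna_only"):
            raise InputError("utility_mode rna_only must coincide with venn cell rna_only")


@dataclass(frozen=True)
class CohortSummary:
    """Counts and one-decimal percentages over a concordance cohort."""

    n_total: int
    counts: dict[str, int]
    percentages: dict[str, float]


def _venn_cell(dna_flag: bool, rna_flag: bool) -> str:
    if dna_flag and rna_flag:
        return "both"
    if dna_flag:
        return "dna_only"
    if rna_flag:
        return "rna_only"
    return "neither"


def round_half_up(value: float | Decimal, ndigits: int = 1) -> float:
    """Round half away from zero to ``ndigits`` decimals (printed convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int) -> float:
    """100 * count / total, rounded half-up to one decimal."""
    if total <= 0:
        raise InputError("percentage of an empty cohort is undefined")
    exact = (Decimal(count) * 100) / Decimal(total)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def expression_support_check(
    dna_gene: str,
    outlier_genes: Iterable[str],
    enriched_groups: Iterable[str],
    downstream_groups: Iterable[str] = (),
) -> str:
    """Level of expression support for one mutated gene.

    ``gene_level`` if the mutated gene itself is an expression outlier;
    otherwise ``downstream`` if any of its downstream pathway groups is
    enriched; otherwise ``none``.
    """
    if dna_gene.upper() in {g.upper() for g in outlier_genes}:
        return "gene_level"
    if set(downstream_groups) & set(enriched_groups):
        return "downstream"
    return "none"


def classify_sample(
    sample_id: str,
    dna: Sequence[MutationFinding],
    rna: Sequence[ActionableFinding],
    enriched_groups: Iterable[str] = (),
    outlier_genes: Iterable[str] | None = None,
) -> ConcordanceRecord:
    """Classify one sample's joint DNA/RNA actionability.

    ``outlier_genes`` is the full set of outlier symbols used for
    gene-level support checks; it defaults to the symbols of the RNA
    actionable findings.
    """
    for f in dna:
        if f.sample_id != sample_id:
            raise InputError(f"DNA finding for {f.sample_id} passed with sample {sample_id}")
    for f in rna:
        if f.sample_id and f.sample_id != sample_id:
            raise InputError(f"RNA finding for {f.sample_id} passed with sample {sample_id}")

    if outlier_genes is None:
        outlier_genes = [f.symbol for f in rna]
    outlier_genes = {g.upper() for g in outlier_genes}
    enriched_groups = set(enriched_groups)

    actionable_dna = [f for f in dna if f.dna_actionable]
    dna_flag = bool(actionable_dna)
    rna_flag = bool(rna)
    cell = _venn_cell(dna_flag, rna_flag)

    support_level = {
        f: expression_support_check(
            f.gene, outlier_genes, enriched_groups, f.downstream_pathway_groups
        )
        for f in actionable_dna
    }
    supported = [f for f in actionable_dna if support_level[f] != "none"]
    dna_genes = {f.gene.upper() for f in actionable_dna}

    evidence = tuple(
        sorted(f"{f.gene}:{support_level[f]}" for f in actionable_dna)
    )

    if cell == "rna_only":
        mode = "rna_only"
    elif len(dna_genes) == 1 and supported:
        mode = "support"
    elif len(dna_genes) >= 2 and supported:
        mode = "prioritize"
    elif any(
        f.rna_mutant_allele_expressed is False and support_level[f] == "none"
        for f in actionable_dna
    ):
        mode = "deprioritize"
    else:
        mode = "none"

    return ConcordanceRecord(
        sample_id=sample_id,
        dna_flag=dna_flag,
        rna_flag=rna_flag,
        venn_cell=cell,
        utility_mode=mode,
        evidence=evidence,
    )


def summarize_cohort(records: Sequence[ConcordanceRecord]) -> CohortSummary:
    """Exact cell counts and one-decimal percentages for a cohort.

    The four Venn cells are exhaustive and disjoint, so their counts sum
    to ``n_total``; ``dna_actionable`` and ``rna_actionable`` are the
    margins (both + dna_only, both + rna_only).
    """
    if not records:
        raise InputError("summarize_cohort: empty cohort")
    n = len(records)
    counts = {cell: 0 for cell in VENN_CELLS}
    for r in records:
        counts[r.venn_cell] += 1
    counts["dna_actionable"] = counts["both"] + counts["dna_only"]
    counts["rna_actionable"] = counts["both"] + counts["rna_only"]
    percentages = {key: percentage(c, n) for key, c in counts.items()}
    return CohortSummary(n_total=n, counts=counts, percentages=percentages)


def venn_table(summary: CohortSummary) -> list[list[object]]:
    """The 2x2 contingency layout of the four Venn cells."""
    c = summary.counts
    return [
        ["", "RNA+", "RNA-"],
        ["DNA+", c["both"], c["dna_only"]],
        ["DNA-", c["rna_only"], c["neither"]],
    ]
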