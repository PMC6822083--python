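"""End-to-end orchestration: QC -> outlier calls -> actionability ->
enrichment -> concordance, per sample and per cohort.

Every effective parameter is echoed into a provenance block written next
to the results, and all outputs are plain TSV/JSON with deterministic
ordering and formatting: two runs with identical inputs and configuration
produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from . import io as pio
from .concordance import (
    ConcordanceRecord,
    classify_sample,
    percentage,
    summarize_cohort,
    venn_table,
)
from .druggability import (
    ActionableFinding,
    annotate_drugs,
    flag_actionable_sample,
    intersect_actionable,
)
from .enrichment import enrich, pathway_outlier_summary
from .errors import ConfigError
from .io import ExpressionCompendium, FocusSample, QCRule, apply_qc, restrict_gene_universe
from .outliers import (
    CohortSpec,
    OutlierLists,
    OutlierParams,
    call_outliers,
    combine_lists,
    select_pan_disease_cohort,
)

LIST_NAMES = ("pan_cancer", "pan_disease", "intersection")
FLOAT_FORMAT = "%.6g"


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    matrix: str
    annotation: str
    metadata: str
    focus: str
    actionable: str
    drugs: str
    gene_sets: str
    group_map: str
    dna: str | None = None
    disease_groups: str | None = None
    out_dir: str = "results"
    seed: int = 0
    iqr_multiplier: float = 1.5
    min_log_expression: float = 2.5
    min_cohort_size: int = 20
    cohort_k: int = 100
    n_variable_genes: int = 1000
    q_cut: float = 0.05
    max_report: int = 100
    qc_min_expressed_genes: int = 10_000
    qc_min_total_tpm_log_sum: float | None = None

    @property
    def outlier_params(self) -> OutlierParams:
        return OutlierParams(
            iqr_multiplier=self.iqr_multiplier,
            min_log_expression=self.min_log_expression,
            min_cohort_size=self.min_cohort_size,
        )

    @property
    def qc_rule(self) -> QCRule:
        return QCRule(
            min_expressed_genes=self.qc_min_expressed_genes,
            min_total_tpm_log_sum=self.qc_min_total_tpm_log_sum,
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle)
        return cls(**data)

    def provenance(self) -> dict:
        config = asdict(self)
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest()
        return {"config": config, "config_sha256": digest, "version": __version__}


@dataclass
class Workspace:
    """All loaded inputs of a run."""

    compendium: ExpressionCompendium
    focus_samples: list[FocusSample]
    actionable: object
    drugs: object
    collection: object
    group_map: dict[str, list[str]]
    dna: dict[str, list] | None = None
    disease_groups: dict[str, str] | None = None


def load_workspace(config: PipelineConfig) -> Workspace:
    compendium = pio.load_compendium(config.matrix, config.annotation, config.metadata)
    focus = pio.read_focus_samples(config.focus)
    dna = pio.read_dna_findings(config.dna) if config.dna else None
    disease_groups = None
    if config.disease_groups:
        df = pd.read_csv(config.disease_groups, sep="\t", dtype=str)
        disease_groups = dict(zip(df["disease"], df["disease_group"]))
    return Workspace(
        compendium=compendium,
        focus_samples=focus,
        actionable=pio.read_actionable_table(config.actionable),
        drugs=pio.read_drug_table(config.drugs),
        collection=pio.read_gene_sets(config.gene_sets),
        group_map=pio.read_group_map(config.group_map),
        dna=dna,
        disease_groups=disease_groups,
    )


@dataclass
class SampleReport:
    sample_id: str
    qc_status: str
    qc_metrics: dict[str, float] = field(default_factory=dict)
    qc_reasons: list[str] = field(default_factory=list)
    pan_cancer_calls: pd.DataFrame | None = None
    pan_disease_calls: pd.DataFrame | None = None
    cohort: CohortSpec | None = None
    lists: OutlierLists | None = None
    findings: list[ActionableFinding] = field(default_factory=list)
    enrichment: dict[str, pd.DataFrame] = field(default_factory=dict)
    pathway_summary: dict = field(default_factory=dict)
    concordance: ConcordanceRecord | None = None
    concordance_status: str = "not_evaluated"
    provenance: dict = field(default_factory=dict)

    @property
    def rna_actionable(self) -> bool:
        return flag_actionable_sample(self.findings)


def run_sample(workspace: Workspace, sample: FocusSample, config: PipelineConfig) -> SampleReport:
    """Run the full per-sample analysis.

    Failed-QC samples yield a report with the QC section only; the
    concordance section is ``not_evaluated`` when no DNA findings file
    covers the sample.
    """
    report = SampleReport(sample_id=sample.sample_id, qc_status="pending",
                          provenance=config.provenance())
    passing, failing = apply_qc([sample], config.qc_rule)
    report.qc_metrics = dict(sample.qc_metrics)
    if failing:
        report.qc_status = "fail"
        report.qc_reasons = failing[0][1]
        return report
    report.qc_status = "pass"

    compendium = workspace.compendium
    symbols = {gid: str(s).upper() for gid, s in compendium.genes["symbol"].items()}
    params = config.outlier_params

    # pan-cancer: whole compendium, filtered universe
    filtered = restrict_gene_universe(compendium, "filtered")
    report.pan_cancer_calls = call_outliers(sample, filtered, params, track="pan_cancer")

    # pan-disease: most-similar cohort, unfiltered universe
    cohort_spec = select_pan_disease_cohort(
        sample,
        compendium,
        k=config.cohort_k,
        n_variable_genes=config.n_variable_genes,
        min_cohort_size=config.min_cohort_size,
    )
    report.cohort = cohort_spec
    cohort_slice = ExpressionCompendium(
        tpm=compendium.tpm[list(cohort_spec.member_ids)],
        genes=compendium.genes,
        metadata=compendium.metadata.loc[list(cohort_spec.member_ids)],
    )
    report.pan_disease_calls = call_outliers(sample, cohort_slice, params, track="pan_disease")

    report.lists = combine_lists(report.pan_cancer_calls, report.pan_disease_calls, symbols)
    findings = intersect_actionable(report.lists, workspace.actionable, sample.sample_id)
    report.findings = annotate_drugs(findings, workspace.drugs)

    filtered_symbols = {symbols[g] for g in filtered.tpm.index}
    all_symbols = set(symbols.values())
    universes = {
        "pan_cancer": filtered_symbols,
        "pan_disease": all_symbols,
        "intersection": filtered_symbols,
    }
    gene_lists = {
        "pan_cancer": report.lists.pan_cancer,
        "pan_disease": report.lists.pan_disease,
        "intersection": report.lists.intersection,
    }
    enriched_sets: set[str] = set()
    for name in LIST_NAMES:
        collection = workspace.collection.with_universe(universes[name])
        result = enrich(
            gene_lists[name], collection, q_cut=config.q_cut, max_report=config.max_report
        )
        report.enrichment[name] = result
        enriched_sets |= set(result["set_name"])

    report.pathway_summary = pathway_outlier_summary(
        report.findings, enriched_sets, workspace.group_map
    )

    if workspace.dna is not None and sample.sample_id in workspace.dna:
        enriched_groups = {
            g for g, flags in report.pathway_summary.items() if flags["set_enriched"]
        }
        report.concordance = classify_sample(
            sample.sample_id,
            workspace.dna[sample.sample_id],
            report.findings,
            enriched_groups=enriched_groups,
            outlier_genes=report.lists.union,
        )
        report.concordance_status = "evaluated"
    return report


def run_cohort(
    workspace: Workspace, config: PipelineConfig, samples: Sequence[FocusSample] | None = None
) -> tuple[list[SampleReport], dict, pd.DataFrame]:
    """Run every sample and aggregate cohort-level results.

    Returns the per-sample reports, a cohort summary dict (RNA
    actionability over all passing samples; the Venn partition over the
    subset with DNA findings), and the recurrence table of actionable
    outliers by disease group.
    """
    samples = list(samples) if samples is not None else workspace.focus_samples
    if not samples:
        raise ConfigError("run_cohort requires at least one sample")
    reports = [run_sample(workspace, s, config) for s in samples]

    passing = [r for r in reports if r.qc_status == "pass"]
    n_rna = sum(r.rna_actionable for r in passing)
    summary: dict = {
        "n_samples": len(reports),
        "n_pass_qc": len(passing),
        "n_rna_actionable": n_rna,
        "pct_rna_actionable": None if not passing else percentage(n_rna, len(passing)),
    }
    concordant = [r.concordance for r in reports if r.concordance is not None]
    if concordant:
        cohort = summarize_cohort(concordant)
        summary["concordance"] = {
            "n_total": cohort.n_total,
            "counts": cohort.counts,
            "percentages": cohort.percentages,
            "venn_table": venn_table(cohort),
        }

    recurrence = recurrence_table(reports, workspace, passing_only=True)
    return reports, summary, recurrence


def recurrence_table(
    reports: Sequence[SampleReport], workspace: Workspace, passing_only: bool = True
) -> pd.DataFrame:
    """Long-format recurrence of actionable outliers: one row per
    (gene, disease group) observed in >= 1 sample, with sample count and
    the supporting analysis tracks."""
    groups = workspace.disease_groups or {}
    cells: dict[tuple[str, str], dict] = {}
    for report in reports:
        if passing_only and report.qc_status != "pass":
            continue
        meta = workspace.compendium.metadata
        disease = None
        for f in report.findings:
            sid = report.sample_id
            disease = disease or (
                meta.loc[sid, "disease"] if sid in meta.index else _focus_disease(workspace, sid)
            )
            group = groups.get(disease, disease) if disease else "other"
            key = (f.symbol, group)
            cell = cells.setdefault(key, {"n_samples": 0, "tracks": set()})
            cell["n_samples"] += 1
            cell["tracks"] |= set(f.tracks)
    rows = [
        (gene, group, cell["n_samples"], "|".join(sorted(cell["tracks"])))
        for (gene, group), cell in sorted(cells.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "disease_group", "n_samples", "tracks"])


def _focus_disease(workspace: Workspace, sample_id: str) -> str | None:
    for s in workspace.focus_samples:
        if s.sample_id == sample_id:
            return s.disease
    return None


# ---------------------------------------------------------------------------
# report writing


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True)
        handle.write("\n")


def write_sample_report(report: SampleReport, outdir: str | Path) -> Path:
    """Write one sample's report tree; returns the sample directory."""
    outdir = Path(outdir) / report.sample_id
    outdir.mkdir(parents=True, exist_ok=True)
    _json_dump(
        {
            "sample_id": report.sample_id,
            "qc_status": report.qc_status,
            "qc_metrics": report.qc_metrics,
            "qc_reasons": report.qc_reasons,
        },
        outdir / "qc.json",
    )
    _json_dump(report.provenance, outdir / "provenance.json")
    if report.qc_status != "pass":
        return outdir

    for track, calls in (
        ("pan_cancer", report.pan_cancer_calls),
        ("pan_disease", report.pan_disease_calls),
    ):
        out = calls.copy()
        out.insert(0, "sample_id", report.sample_id)
        out.to_csv(outdir / f"outliers_{track}.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)

    _json_dump(
        {
            "pan_cancer": sorted(report.lists.pan_cancer),
            "pan_disease": sorted(report.lists.pan_disease),
            "intersection": sorted(report.lists.intersection),
        },
        outdir / "outlier_lists.json",
    )
    findings_df = pd.DataFrame(
        [
            (
                f.sample_id,
                f.symbol,
                f.klass,
                f.pathway_group,
                "|".join(sorted(f.tracks)),
                ";".join(f"{d}[{s}]" for d, s in f.drugs),
            )
            for f in report.findings
        ],
        columns=["sample_id", "gene", "class", "pathway_group", "tracks", "drugs"],
    )
    findings_df.to_csv(outdir / "actionable_findings.tsv", sep="\t", index=False)
    for name, result in report.enrichment.items():
        out = result.copy()
        out.insert(0, "list_name", name)
        out.insert(0, "sample_id", report.sample_id)
        out.to_csv(outdir / f"enrichment_{name}.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
    _json_dump(report.pathway_summary, outdir / "pathway_summary.json")
    if report.concordance is not None:
        record = report.concordance
        _json_dump(
            {
                "sample_id": record.sample_id,
                "dna_flag": record.dna_flag,
                "rna_flag": record.rna_flag,
                "venn_cell": record.venn_cell,
                "utility_mode": record.utility_mode,
                "evidence": list(record.evidence),
            },
            outdir / "concordance.json",
        )
    else:
        _json_dump({"status": report.concordance_status}, outdir / "concordance.json")
    return outdir


def write_cohort_outputs(
    reports: Sequence[SampleReport], summary: dict, recurrence: pd.DataFrame, outdir: str | Path
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for report in reports:
        write_sample_report(report, outdir)
    _json_dump(summary, outdir / "cohort_summary.json")
    recurrence.to_csv(outdir / "recurrence.tsv", sep="\t", index=False)
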