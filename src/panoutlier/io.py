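"""Readers, writers and containers for the expression compendium workspace.

All on-disk formats are plain text: a tab-separated gene x sample TPM
matrix (header row = sample ids, first column = gene ids), TSV gene
annotation and sample metadata, GMT gene-set collections, and TSV
actionable-gene / drug-gene tables. TPM values are stored untransformed;
every log transform happens at the point of analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .druggability import ActionableGene, ActionableGeneList, DrugGeneTable
from .enrichment import GeneSetCollection
from .errors import ConfigError, FormatError

GENE_UNIVERSES = ("filtered", "unfiltered")


@dataclass(frozen=True)
class GeneRecord:
    """Annotation for one gene: stable id, symbol, and whether it belongs
    to the filtered (pan-cancer) gene universe."""

    gene_id: str
    symbol: str
    in_filtered_universe: bool


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    disease: str
    age_at_diagnosis: float | None = None
    sex: str | None = None
    site: str | None = None
    patient_id: str | None = None

    def __post_init__(self) -> None:
        if not self.disease:
            raise FormatError(f"sample {self.sample_id} has an empty disease label")


@dataclass
class ExpressionCompendium:
    """A reference collection of uniformly processed tumor expression profiles.

    ``tpm`` is a genes x samples DataFrame (index = gene ids, columns =
    sample ids); ``genes`` an annotation DataFrame indexed by gene id with
    ``symbol`` and ``in_filtered_universe`` columns; ``metadata`` a
    DataFrame indexed by sample id with at least a ``disease`` column.

    ``disease_log_means`` and ``log_sd`` are ground-truth parameters kept
    by the synthetic generator (genes x diseases mean log2(TPM+1) and the
    residual log2 sd); they are None for compendia read from disk unless a
    ground-truth file is supplied.
    """

    tpm: pd.DataFrame
    genes: pd.DataFrame
    metadata: pd.DataFrame
    disease_log_means: pd.DataFrame | None = None
    log_sd: float | None = None

    def __post_init__(self) -> None:
        if not self.tpm.index.equals(self.genes.index):
            raise FormatError("expression matrix gene ids do not match annotation")
        if not self.tpm.index.is_unique:
            raise FormatError("duplicate gene ids in compendium")
        missing = set(self.tpm.columns) - set(self.metadata.index)
        if missing:
            raise FormatError(f"samples without metadata: {sorted(missing)[:5]}")
        if (self.tpm.to_numpy() < 0).any():
            raise FormatError("negative TPM values in compendium")

    @property
    def n_genes(self) -> int:
        return self.tpm.shape[0]

    @property
    def n_samples(self) -> int:
        return self.tpm.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tpm.columns)

    @property
    def symbols(self) -> pd.Series:
        return self.genes["symbol"]

    def gene_records(self) -> list[GeneRecord]:
        return [
            GeneRecord(gid, row.symbol, bool(row.in_filtered_universe))
            for gid, row in self.genes.iterrows()
        ]


@dataclass
class FocusSample:
    """One patient tumor TPM vector aligned to a compendium's gene list."""

    sample_id: str
    tpm: pd.Series
    qc_metrics: dict[str, float] = field(default_factory=dict)
    disease: str | None = None
    truth_spikes: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if (self.tpm.to_numpy() < 0).any():
            raise FormatError(f"negative TPM values in focus sample {self.sample_id}")


@dataclass(frozen=True)
class QCRule:
    """Configurable sample-level quality rule.

    The default requires at least 10,000 genes with nonzero TPM, a proxy
    for library complexity; an optional floor on the per-sample sum of
    log2(TPM+1) guards against degenerate near-empty libraries.
    """

    min_expressed_genes: int = 10_000
    min_total_tpm_log_sum: float | None = None

    def __post_init__(self) -> None:
        if self.min_expressed_genes < 0:
            raise ConfigError("min_expressed_genes must be >= 0")
        if self.min_total_tpm_log_sum is not None and self.min_total_tpm_log_sum < 0:
            raise ConfigError("min_total_tpm_log_sum must be >= 0")


# ---------------------------------------------------------------------------
# expression matrix


def read_expression_matrix(path: str | Path, orientation: str = "genes_by_samples") -> pd.DataFrame:
    """Read a TSV TPM matrix into a genes x samples DataFrame.

    ``orientation='samples_by_genes'`` accepts the transpose and returns
    the canonical genes x samples layout. Duplicate gene ids, missing
    values and negative entries are format errors.
    """
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ConfigError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "samples_by_genes":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if not df.index.is_unique:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene ids {dupes[:5]}")
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise FormatError(f"{path}: missing or non-numeric value at gene {gene!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc
    if (values < 0).any():
        gene = df.index[(values < 0).any(axis=1)][0]
        raise FormatError(f"{path}: negative TPM at gene {gene!r}")
    return df.astype(float)


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


# ---------------------------------------------------------------------------
# gene annotation and sample metadata


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "symbol": str})
    required = {"gene_id", "symbol", "in_filtered_universe"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: gene annotation needs columns {sorted(required)}")
    if df["gene_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene ids in annotation")
    df = df.set_index("gene_id")
    df["in_filtered_universe"] = df["in_filtered_universe"].astype(bool)
    return df


def write_gene_annotation(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns or "disease" not in df.columns:
        raise FormatError(f"{path}: metadata needs sample_id and disease columns")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids in metadata")
    if df["disease"].isna().any() or (df["disease"].astype(str) == "").any():
        raise FormatError(f"{path}: empty disease label")
    return df.set_index("sample_id")


def write_sample_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def load_compendium(
    matrix_path: str | Path,
    annotation_path: str | Path,
    metadata_path: str | Path,
    orientation: str = "genes_by_samples",
) -> ExpressionCompendium:
    tpm = read_expression_matrix(matrix_path, orientation)
    genes = read_gene_annotation(annotation_path).reindex(tpm.index)
    if genes["symbol"].isna().any():
        missing = tpm.index[genes["symbol"].isna()][:5].tolist()
        raise FormatError(f"genes missing from annotation: {missing}")
    metadata = read_sample_metadata(metadata_path)
    return ExpressionCompendium(tpm=tpm, genes=genes, metadata=metadata)


# ---------------------------------------------------------------------------
# focus samples


def read_focus_samples(path: str | Path, orientation: str = "genes_by_samples") -> list[FocusSample]:
    """Read one or more focus-sample TPM vectors from a matrix-shaped TSV."""
    df = read_expression_matrix(path, orientation)
    return [FocusSample(sample_id=c, tpm=df[c]) for c in df.columns]


def write_focus_samples(samples: Sequence[FocusSample], path: str | Path) -> None:
    df = pd.DataFrame({s.sample_id: s.tpm for s in samples})
    write_expression_matrix(df, path)


# ---------------------------------------------------------------------------
# QC and universe restriction


def qc_metrics(sample: FocusSample) -> dict[str, float]:
    values = sample.tpm.to_numpy(dtype=float)
    return {
        "expressed_genes": float((values > 0).sum()),
        "total_tpm_log_sum": float(np.log2(values + 1.0).sum()),
    }


def apply_qc(
    samples: Sequence[FocusSample], rule: QCRule
) -> tuple[list[FocusSample], list[tuple[FocusSample, list[str]]]]:
    """Partition samples into passing and failing (with violated criteria).

    The partition is exhaustive and disjoint; metrics are recorded on each
    sample's ``qc_metrics``.
    """
    passing: list[FocusSample] = []
    failing: list[tuple[FocusSample, list[str]]] = []
    for sample in samples:
        metrics = qc_metrics(sample)
        sample.qc_metrics.update(metrics)
        reasons = []
        if metrics["expressed_genes"] < rule.min_expressed_genes:
            reasons.append(
                f"expressed_genes {metrics['expressed_genes']:.0f} < {rule.min_expressed_genes}"
            )
        if (
            rule.min_total_tpm_log_sum is not None
            and metrics["total_tpm_log_sum"] < rule.min_total_tpm_log_sum
        ):
            reasons.append(
                f"total_tpm_log_sum {metrics['total_tpm_log_sum']:.1f} < {rule.min_total_tpm_log_sum}"
            )
        if reasons:
            failing.append((sample, reasons))
        else:
            passing.append(sample)
    return passing, failing


def restrict_gene_universe(compendium: ExpressionCompendium, universe: str) -> ExpressionCompendium:
    """Restrict to the filtered (pan-cancer) gene universe, or return the
    compendium unchanged for the unfiltered (pan-disease) universe.

    Retained genes keep their original order; the operation is idempotent.
    """
    if universe not in GENE_UNIVERSES:
        raise ConfigError(f"unknown gene universe {universe!r}")
    if universe == "unfiltered":
        return compendium
    keep = compendium.genes["in_filtered_universe"].to_numpy(dtype=bool)
    return ExpressionCompendium(
        tpm=compendium.tpm.loc[keep],
        genes=compendium.genes.loc[keep],
        metadata=compendium.metadata,
        disease_log_means=(
            compendium.disease_log_means.loc[keep]
            if compendium.disease_log_means is not None
            else None
        ),
        log_sd=compendium.log_sd,
    )


# ---------------------------------------------------------------------------
# gene sets, actionable table, drug table


def read_gene_sets(path: str | Path, universe_size: int | None = None) -> GeneSetCollection:
    """Read a GMT file (name <TAB> description <TAB> member genes...).

    ``universe_size`` defaults to the size of the union of all members;
    analyses should rebind it to the active gene universe.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name, _desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = frozenset(members)
    union: set[str] = set()
    for members in sets.values():
        union |= members
    if universe_size is None:
        universe_size = len(union)
    return GeneSetCollection(sets=sets, universe_size=universe_size)


def write_gene_sets(collection: GeneSetCollection, path: str | Path, descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as handle:
        for name in sorted(collection.sets):
            desc = descriptions.get(name, "na")
            members = "\t".join(sorted(collection.sets[name]))
            handle.write(f"{name}\t{desc}\t{members}\n")


def read_actionable_table(path: str | Path) -> ActionableGeneList:
    """Read the curated actionable-gene TSV (symbol, class, pathway_group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"symbol", "class", "pathway_group"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: actionable table needs columns {sorted(required)}")
    entries = tuple(
        ActionableGene(symbol=s, klass=c, pathway_group=g)
        for s, c, g in zip(df["symbol"], df["class"], df["pathway_group"])
    )
    return ActionableGeneList(entries=entries)


def write_actionable_table(table: ActionableGeneList, path: str | Path) -> None:
    df = pd.DataFrame(
        [(e.symbol, e.klass, e.pathway_group) for e in table.entries],
        columns=["symbol", "class", "pathway_group"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_drug_table(path: str | Path) -> DrugGeneTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"symbol", "drug", "source"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: drug table needs columns {sorted(required)}")
    rows = tuple((r.symbol, r.drug, r.source) for r in df.itertuples(index=False))
    return DrugGeneTable(rows=rows)


def write_drug_table(table: DrugGeneTable, path: str | Path) -> None:
    df = pd.DataFrame(list(table.rows), columns=["symbol", "drug", "source"])
    df.to_csv(path, sep="\t", index=False)


def read_group_map(path: str | Path) -> dict[str, list[str]]:
    """Pathway-group to gene-set-name mapping (TSV: pathway_group, set_name)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"pathway_group", "set_name"} <= set(df.columns):
        raise FormatError(f"{path}: group map needs pathway_group and set_name columns")
    mapping: dict[str, list[str]] = {}
    for r in df.itertuples(index=False):
        mapping.setdefault(r.pathway_group, []).append(r.set_name)
    return mapping


def read_dna_findings(path: str | Path) -> dict[str, list]:
    """Per-sample DNA mutation findings from a TSV.

    Columns: sample_id, gene, variant, class, dna_actionable,
    allele_expressed (may be empty = unknown), downstream_groups
    (semicolon-joined pathway group labels).
    """
    from .concordance import MutationFinding

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "gene", "variant", "class", "dna_actionable"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: DNA findings need columns {sorted(required)}")

    def to_bool(value: str) -> bool | None:
        if value == "":
            return None
        return value.strip().lower() in ("true", "1", "yes")

    findings: dict[str, list] = {}
    for row in df.to_dict("records"):
        groups = frozenset(
            g for g in str(row.get("downstream_groups", "")).split(";") if g
        )
        finding = MutationFinding(
            sample_id=row["sample_id"],
            gene=row["gene"],
            variant=row["variant"],
            variant_class=row["class"],
            dna_actionable=bool(to_bool(row["dna_actionable"])),
            rna_mutant_allele_expressed=to_bool(row.get("allele_expressed", "")),
            downstream_pathway_groups=groups,
        )
        findings.setdefault(row["sample_id"], []).append(finding)
    return findings


def read_downstream_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Gene to downstream pathway-group mapping (semicolon-joined groups)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "downstream_groups"} <= set(df.columns):
        raise FormatError(f"{path}: downstream map needs gene and downstream_groups columns")
    return {
        r.gene.upper(): frozenset(g for g in str(r.downstream_groups).split(";") if g)
        for r in df.itertuples(index=False)
    }
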