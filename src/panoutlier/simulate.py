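"""Synthetic compendium, focus-sample and DNA-finding generators.

These generators stand in for the reference tumor compendium and patient
tumors so that every downstream stage is testable with no external data.
Expression is modeled as log-normal in log2(TPM+1) space: each gene has a
baseline mean, each (disease, gene) pair a fixed offset drawn once at
compendium creation, and each observation adds Gaussian noise; TPM is
recovered as ``2**x - 1`` truncated at zero. That captures the right
skew of TPM without attempting to estimate any real cohort's noise. Ages
are drawn uniformly on [0, 30) for pediatric samples and [30, 80)
otherwise — only the under-30 fraction matters to any statistic computed
here.

Ground truth (spiked genes, disease means, concordance cells) is always
returned next to the data so recovery tests never re-derive it.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .concordance import MutationFinding, VENN_CELLS
from .druggability import ActionableGeneList
from .enrichment import GeneSetCollection
from .errors import ConfigError, InputError
from .io import ExpressionCompendium, FocusSample

CONCORDANCE_SCENARIOS = ("both", "dna_only", "rna_only", "neither", "mixed")

#: Cell probabilities of the "mixed" concordance scenario
#: (both, dna_only, rna_only, neither).
MIXED_CELL_PROBS = (28 / 74, 6 / 74, 27 / 74, 13 / 74)


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of the synthetic compendium.

    Defaults: 2,000 genes x 500 tumors over 5 disease labels with a
    pediatric (under-30) fraction of 0.164; baseline mean 3.0 and
    residual sd 0.8 in log2(TPM+1), disease offsets with sd 1.0 — typical
    magnitudes for within-disease dispersion and between-disease
    separation of bulk tumor expression.
    """

    n_genes: int = 2000
    n_samples: int = 500
    n_diseases: int = 5
    pediatric_fraction: float = 0.164
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 0.8
    disease_shift_sd: float = 1.0
    spike_genes: tuple[tuple[str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1 or self.n_diseases < 1:
            raise ConfigError("n_genes, n_samples and n_diseases must be positive")
        if self.n_diseases > self.n_samples:
            raise ConfigError("n_diseases cannot exceed n_samples")
        if not 0.0 <= self.pediatric_fraction <= 1.0:
            raise ConfigError("pediatric_fraction must lie in [0, 1]")
        if self.baseline_log_sd < 0 or self.disease_shift_sd < 0:
            raise ConfigError("standard deviations must be >= 0")


def default_actionable_table() -> ActionableGeneList:
    """The packaged synthetic stand-in for the 92-gene actionable table."""
    path = importlib.resources.files("panoutlier.data") / "actionable_genes_synthetic.tsv"
    return pio.read_actionable_table(str(path))


def default_drug_table():
    path = importlib.resources.files("panoutlier.data") / "drug_gene_synthetic.tsv"
    return pio.read_drug_table(str(path))


def default_downstream_map() -> dict[str, frozenset[str]]:
    path = importlib.resources.files("panoutlier.data") / "downstream_groups_synthetic.tsv"
    return pio.read_downstream_map(str(path))


def _gene_tables(config: SimulationConfig) -> pd.DataFrame:
    """Gene annotation: the actionable symbols head the gene list so that
    spiked drivers can hit the actionable table; all actionable genes sit
    in the filtered universe, the rest alternate."""
    actionable = [e.symbol for e in default_actionable_table().entries]
    symbols = []
    for i in range(config.n_genes):
        if i < len(actionable):
            symbols.append(actionable[i])
        else:
            symbols.append(f"GENE{i:05d}")
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    in_filtered = [i < len(actionable) or i % 2 == 0 for i in range(config.n_genes)]
    return pd.DataFrame(
        {"symbol": symbols, "in_filtered_universe": in_filtered},
        index=pd.Index(gene_ids, name="gene_id"),
    )


def generate_compendium(config: SimulationConfig) -> ExpressionCompendium:
    """Simulate a reference compendium under ``config``.

    Samples are assigned disease labels cyclically (balanced design);
    per-(disease, gene) mean offsets are drawn once and stored on the
    returned compendium as ground truth, so focus samples generated later
    are exchangeable with compendium members of the same disease.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_tables(config)
    diseases = [f"D{d:02d}" for d in range(config.n_diseases)]
    disease_of = [diseases[i % config.n_diseases] for i in range(config.n_samples)]
    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]

    offsets = rng.normal(0.0, config.disease_shift_sd, size=(config.n_genes, config.n_diseases))
    disease_log_means = pd.DataFrame(
        config.baseline_log_mean + offsets, index=genes.index, columns=diseases
    )
    disease_idx = np.array([diseases.index(d) for d in disease_of])
    log_values = (
        disease_log_means.to_numpy()[:, disease_idx]
        + rng.normal(0.0, config.baseline_log_sd, size=(config.n_genes, config.n_samples))
    )
    tpm = np.maximum(np.exp2(log_values) - 1.0, 0.0)

    pediatric = rng.random(config.n_samples) < config.pediatric_fraction
    ages = np.where(
        pediatric,
        rng.uniform(0.0, 30.0, config.n_samples),
        rng.uniform(30.0, 80.0, config.n_samples),
    )
    sexes = rng.choice(["F", "M"], size=config.n_samples)
    metadata = pd.DataFrame(
        {
            "disease": disease_of,
            "age_at_diagnosis": np.round(ages, 1),
            "sex": sexes,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionCompendium(
        tpm=pd.DataFrame(tpm, index=genes.index, columns=sample_ids),
        genes=genes,
        metadata=metadata,
        disease_log_means=disease_log_means,
        log_sd=config.baseline_log_sd,
    )


def _resolve_gene_ids(compendium: ExpressionCompendium, genes: Sequence[str]) -> list[str]:
    """Accept either gene ids or symbols; return gene ids."""
    by_symbol = {str(s).upper(): gid for gid, s in compendium.genes["symbol"].items()}
    resolved = []
    for g in genes:
        if g in compendium.genes.index:
            resolved.append(g)
        elif str(g).upper() in by_symbol:
            resolved.append(by_symbol[str(g).upper()])
        else:
            raise InputError(f"unknown gene {g!r}")
    return resolved


def generate_focus_sample(
    compendium: ExpressionCompendium,
    disease: str,
    spikes: Sequence[tuple[str, float]] = (),
    seed: int = 0,
    sample_id: str = "FOCUS",
) -> FocusSample:
    """Draw one focus tumor from a disease's distribution, with optional
    log2 spikes on named genes (the ground-truth overexpressed drivers).

    Synthetic compendia carry their generative disease means and noise sd;
    for a compendium read from disk both are estimated from the data (the
    per-disease mean of log2(TPM+1) and the pooled within-disease residual
    sd), so focus samples stay approximately exchangeable with members.
    """
    if compendium.disease_log_means is not None and compendium.log_sd is not None:
        if disease not in compendium.disease_log_means.columns:
            raise InputError(f"unknown disease {disease!r}")
        mean_table = compendium.disease_log_means
        log_sd = compendium.log_sd
    else:
        diseases = compendium.metadata.loc[compendium.sample_ids, "disease"]
        if disease not in set(diseases):
            raise InputError(f"unknown disease {disease!r}")
        L = pd.DataFrame(
            np.log2(compendium.tpm.to_numpy() + 1.0),
            index=compendium.tpm.index,
            columns=compendium.tpm.columns,
        )
        mean_table = L.T.groupby(diseases).mean().T
        residuals = L - mean_table[diseases.to_numpy()].to_numpy()
        log_sd = float(residuals.to_numpy().std(ddof=1))
    spike_ids = _resolve_gene_ids(compendium, [g for g, _ in spikes])

    rng = np.random.default_rng(seed)
    means = mean_table[disease].to_numpy().copy()
    for gid, (_, effect) in zip(spike_ids, spikes):
        means[compendium.tpm.index.get_loc(gid)] += float(effect)
    log_values = means + rng.normal(0.0, log_sd, size=compendium.n_genes)
    tpm = np.maximum(np.exp2(log_values) - 1.0, 0.0)
    return FocusSample(
        sample_id=sample_id,
        tpm=pd.Series(tpm, index=compendium.tpm.index),
        disease=disease,
        truth_spikes=tuple((gid, float(e)) for gid, (_, e) in zip(spike_ids, spikes)),
    )


@dataclass(frozen=True)
class ConcordanceScenario:
    """DNA findings plus the constructed ground truth for each sample."""

    findings: dict[str, list[MutationFinding]]
    rna_actionable_genes: dict[str, tuple[str, ...]]
    truth_cells: dict[str, str]


def generate_dna_findings(
    sample_ids: Sequence[str],
    scenario: str,
    seed: int = 0,
    cell_probs: Sequence[float] = MIXED_CELL_PROBS,
    actionable: ActionableGeneList | None = None,
) -> ConcordanceScenario:
    """Construct per-sample DNA findings with known concordance cells.

    ``scenario`` fixes the Venn cell of every sample, or, for ``mixed``,
    allocates cells in the exact proportions of ``cell_probs`` (largest
    remainder) and shuffles the assignment with ``seed``, so empirical
    fractions match the target composition by construction while the
    per-sample assignment stays exchangeable.
    """
    if scenario not in CONCORDANCE_SCENARIOS:
        raise ConfigError(f"unknown concordance scenario {scenario!r}")
    actionable = actionable or default_actionable_table()
    direct = [e.symbol for e in actionable.direct]
    rng = np.random.default_rng(seed)

    n = len(sample_ids)
    if scenario == "mixed":
        probs = np.asarray(cell_probs, dtype=float)
        if probs.size != 4 or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ConfigError("cell_probs must be 4 nonnegative values summing to 1")
        counts = np.floor(probs * n).astype(int)
        remainder = probs * n - counts
        for i in np.argsort(-remainder)[: n - counts.sum()]:
            counts[i] += 1
        cells = np.repeat(list(VENN_CELLS), counts)
        rng.shuffle(cells)
    else:
        cells = np.array([scenario] * n)

    findings: dict[str, list[MutationFinding]] = {}
    rna_genes: dict[str, tuple[str, ...]] = {}
    truth: dict[str, str] = {}
    for sid, cell in zip(sample_ids, cells):
        cell = str(cell)
        truth[sid] = cell
        sample_findings: list[MutationFinding] = []
        if cell in ("both", "dna_only"):
            gene = direct[int(rng.integers(len(direct)))]
            sample_findings.append(
                MutationFinding(
                    sample_id=sid,
                    gene=gene,
                    variant="activating",
                    variant_class="SNV",
                    dna_actionable=True,
                )
            )
        findings[sid] = sample_findings
        if cell in ("both", "rna_only"):
            gene = direct[int(rng.integers(len(direct)))]
            rna_genes[sid] = (gene,)
        else:
            rna_genes[sid] = ()
    return ConcordanceScenario(findings=findings, rna_actionable_genes=rna_genes, truth_cells=truth)


# ---------------------------------------------------------------------------
# fixture workspace


def build_gene_set_collection(
    compendium: ExpressionCompendium,
    actionable: ActionableGeneList | None = None,
    n_random_sets: int = 20,
    random_set_size: int = 25,
    seed: int = 0,
) -> tuple[GeneSetCollection, dict[str, list[str]]]:
    """A gene-set collection over the compendium's symbols.

    One set per actionable pathway group (its member genes), plus random
    filler sets; returns the collection and the pathway-group -> set-name
    mapping used by the pathway summary.
    """
    actionable = actionable or default_actionable_table()
    rng = np.random.default_rng(seed)
    universe = [str(s).upper() for s in compendium.genes["symbol"]]
    sets: dict[str, frozenset[str]] = {}
    group_map: dict[str, list[str]] = {}
    groups = sorted({e.pathway_group for e in actionable.entries})
    for group in groups:
        name = "PATHWAY_" + group.upper().replace("-", "_")
        members = frozenset(
            e.symbol.upper() for e in actionable.entries if e.pathway_group == group
        )
        sets[name] = members
        group_map[group] = [name]
    for i in range(n_random_sets):
        members = rng.choice(universe, size=min(random_set_size, len(universe)), replace=False)
        sets[f"RANDOM_SET_{i:03d}"] = frozenset(str(m) for m in members)
    collection = GeneSetCollection(sets=sets, universe_size=len(set(universe)))
    return collection, group_map


def make_fixture_workspace(
    outdir: str | Path,
    config: SimulationConfig | None = None,
    n_focus: int = 6,
    spike_effect: float = 4.0,
    dna_scenario: str = "mixed",
) -> dict[str, Path]:
    """Materialize a complete on-disk workspace for the pipeline.

    Writes the compendium matrix/annotation/metadata, focus samples with
    spiked actionable drivers, the actionable and drug tables, a GMT
    collection with its pathway-group mapping, DNA findings and a
    ground-truth JSON. Returns the path of every artifact.
    """
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or SimulationConfig()
    compendium = generate_compendium(config)
    actionable = default_actionable_table()
    rng = np.random.default_rng(config.seed + 1)

    diseases = list(compendium.disease_log_means.columns)
    direct = [e.symbol for e in actionable.direct]
    focus_samples = []
    truth_spikes = {}
    for i in range(n_focus):
        disease = diseases[i % len(diseases)]
        gene = direct[int(rng.integers(len(direct)))]
        sample = generate_focus_sample(
            compendium,
            disease,
            spikes=[(gene, spike_effect)],
            seed=int(rng.integers(2**31 - 1)),
            sample_id=f"T{i:03d}",
        )
        focus_samples.append(sample)
        truth_spikes[sample.sample_id] = {"disease": disease, "spiked_gene": gene}

    scenario = generate_dna_findings(
        [s.sample_id for s in focus_samples], dna_scenario, seed=config.seed + 2
    )
    downstream = default_downstream_map()
    collection, group_map = build_gene_set_collection(compendium, actionable, seed=config.seed)

    paths = {
        "matrix": outdir / "compendium_tpm.tsv",
        "annotation": outdir / "gene_annotation.tsv",
        "metadata": outdir / "sample_metadata.tsv",
        "focus": outdir / "focus_tpm.tsv",
        "actionable": outdir / "actionable_genes.tsv",
        "drugs": outdir / "drug_gene.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "group_map": outdir / "pathway_group_map.tsv",
        "dna": outdir / "dna_findings.tsv",
        "truth": outdir / "ground_truth.json",
    }
    pio.write_expression_matrix(compendium.tpm, paths["matrix"])
    pio.write_gene_annotation(compendium.genes, paths["annotation"])
    # metadata covers the focus samples too, so cohort-level reports can
    # group findings by disease
    focus_meta = pd.DataFrame(
        {
            "disease": [s.disease for s in focus_samples],
            "age_at_diagnosis": [10.0] * n_focus,
            "sex": ["F" if i % 2 else "M" for i in range(n_focus)],
        },
        index=pd.Index([s.sample_id for s in focus_samples], name="sample_id"),
    )
    pio.write_sample_metadata(pd.concat([compendium.metadata, focus_meta]), paths["metadata"])
    pio.write_focus_samples(focus_samples, paths["focus"])
    pio.write_actionable_table(actionable, paths["actionable"])
    pio.write_drug_table(default_drug_table(), paths["drugs"])
    pio.write_gene_sets(collection, paths["gene_sets"])
    pd.DataFrame(
        [(g, s) for g, names in sorted(group_map.items()) for s in names],
        columns=["pathway_group", "set_name"],
    ).to_csv(paths["group_map"], sep="\t", index=False)

    rows = []
    for sid in sorted(scenario.findings):
        sample_rows = scenario.findings[sid]
        if not sample_rows:
            # DNA data available but nothing actionable: a passenger
            # variant records availability on disk
            sample_rows = [
                MutationFinding(
                    sample_id=sid,
                    gene="TTN",
                    variant="passenger",
                    variant_class="SNV",
                    dna_actionable=False,
                )
            ]
        for f in sample_rows:
            groups = downstream.get(f.gene.upper(), frozenset())
            rows.append(
                (
                    sid,
                    f.gene,
                    f.variant,
                    f.variant_class,
                    f.dna_actionable,
                    "" if f.rna_mutant_allele_expressed is None else f.rna_mutant_allele_expressed,
                    ";".join(sorted(groups)),
                )
            )
    pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "gene",
            "variant",
            "class",
            "dna_actionable",
            "allele_expressed",
            "downstream_groups",
        ],
    ).to_csv(paths["dna"], sep="\t", index=False)

    with open(paths["truth"], "w") as handle:
        json.dump(
            {
                "spikes": truth_spikes,
                "dna_truth_cells": scenario.truth_cells,
                "dna_rna_genes": {k: list(v) for k, v in scenario.rna_actionable_genes.items()},
            },
            handle,
            indent=2,
            sort_keys=True,
        )
    return paths
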