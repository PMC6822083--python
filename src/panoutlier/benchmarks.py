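"""Seeded simulation studies that characterize the pipeline's operating
points: fence sensitivity and false-positive rate, pan-disease cohort
purity, and concordance-cell recovery.

These are the package's own calibration experiments, run at desk scale
(hundreds of samples, thousands of genes) with every random draw derived
from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .concordance import classify_sample
from .druggability import ActionableFinding
from .outliers import OutlierParams, call_outliers, select_pan_disease_cohort
from .simulate import SimulationConfig, generate_compendium, generate_dna_findings, generate_focus_sample


@dataclass(frozen=True)
class SpikeRecoveryResult:
    sensitivity: float
    null_outlier_rate: float
    n_cohort: int
    n_replicates: int
    n_spiked_total: int


def spike_recovery(
    seed: int = 0,
    n_cohort: int = 500,
    n_genes: int = 2000,
    n_replicates: int = 100,
    n_spiked: int = 5,
    effect: float = 4.0,
    params: OutlierParams = OutlierParams(),
) -> SpikeRecoveryResult:
    """Sensitivity of the fence for spiked genes and the per-gene null rate.

    A homogeneous compendium of ``n_cohort`` tumors is generated once; in
    each replicate a focus tumor carries ``n_spiked`` genes shifted up by
    ``effect`` log2 units. Sensitivity is the fraction of spiked genes
    called as outliers; the null rate is the outlier fraction among
    unspiked genes.
    """
    rng = np.random.default_rng(seed)
    config = SimulationConfig(
        n_genes=n_genes,
        n_samples=n_cohort,
        n_diseases=1,
        disease_shift_sd=0.0,
        seed=int(rng.integers(2**31 - 1)),
    )
    compendium = generate_compendium(config)
    gene_ids = list(compendium.tpm.index)

    detected = 0
    total_spiked = 0
    null_calls = 0
    null_genes = 0
    for _ in range(n_replicates):
        spiked = rng.choice(gene_ids, size=n_spiked, replace=False)
        sample = generate_focus_sample(
            compendium,
            "D00",
            spikes=[(g, effect) for g in spiked],
            seed=int(rng.integers(2**31 - 1)),
        )
        calls = call_outliers(sample, compendium, params, "pan_cancer")
        spiked_mask = calls["gene_id"].isin(spiked)
        detected += int(calls.loc[spiked_mask, "is_outlier"].sum())
        total_spiked += n_spiked
        null_calls += int(calls.loc[~spiked_mask, "is_outlier"].sum())
        null_genes += int((~spiked_mask).sum())
    return SpikeRecoveryResult(
        sensitivity=detected / total_spiked,
        null_outlier_rate=null_calls / null_genes,
        n_cohort=n_cohort,
        n_replicates=n_replicates,
        n_spiked_total=total_spiked,
    )


def cohort_selection_purity(
    seed: int = 0,
    n_replicates: int = 50,
    n_genes: int = 1000,
    n_samples: int = 300,
    n_diseases: int = 3,
    disease_shift_sd: float = 2.0,
    k: int = 30,
    n_variable_genes: int = 500,
) -> float:
    """Fraction of replicates whose top-k cohort is majority same-disease.

    The compendium has well-separated disease signatures; each replicate
    draws a focus tumor from one disease and checks that most of its
    selected reference cohort shares that disease label.
    """
    rng = np.random.default_rng(seed)
    config = SimulationConfig(
        n_genes=n_genes,
        n_samples=n_samples,
        n_diseases=n_diseases,
        disease_shift_sd=disease_shift_sd,
        seed=int(rng.integers(2**31 - 1)),
    )
    compendium = generate_compendium(config)
    diseases = list(compendium.disease_log_means.columns)
    majority_hits = 0
    for i in range(n_replicates):
        disease = diseases[i % len(diseases)]
        sample = generate_focus_sample(
            compendium, disease, seed=int(rng.integers(2**31 - 1))
        )
        spec = select_pan_disease_cohort(
            sample, compendium, k=k, n_variable_genes=n_variable_genes
        )
        if spec.disease_composition.get(disease, 0) > k / 2:
            majority_hits += 1
    return majority_hits / n_replicates


@dataclass(frozen=True)
class ConcordanceRecoveryResult:
    recovery: float
    cell_fractions: dict[str, float]
    n_samples: int


def concordance_recovery(seed: int = 0, n_samples: int = 740) -> ConcordanceRecoveryResult:
    """Recovery of constructed concordance cells on the mixed scenario."""
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    scenario = generate_dna_findings(sample_ids, "mixed", seed=seed)
    recovered = 0
    counts = {"both": 0, "dna_only": 0, "rna_only": 0, "neither": 0}
    for sid in sample_ids:
        rna = [
            ActionableFinding(sid, g, "direct", "RTK", frozenset({"pan_cancer"}))
            for g in scenario.rna_actionable_genes[sid]
        ]
        record = classify_sample(sid, scenario.findings[sid], rna)
        counts[record.venn_cell] += 1
        if record.venn_cell == scenario.truth_cells[sid]:
            recovered += 1
    return ConcordanceRecoveryResult(
        recovery=recovered / n_samples,
        cell_fractions={cell: c / n_samples for cell, c in counts.items()},
        n_samples=n_samples,
    )
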