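"""Tests of the synthetic compendium / focus-sample / DNA-finding generators."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from panoutlier.errors import ConfigError, InputError
from panoutlier.outliers import OutlierParams, call_outliers, log2_tpm
from panoutlier.simulate import (
    MIXED_CELL_PROBS,
    SimulationConfig,
    generate_compendium,
    generate_dna_findings,
    generate_focus_sample,
)


class TestGenerateCompendium:
    def test_seeded_determinism(self, small_config):
        a = generate_compendium(small_config)
        b = generate_compendium(small_config)
        pd.testing.assert_frame_equal(a.tpm, b.tpm)
        pd.testing.assert_frame_equal(a.metadata, b.metadata)
        pd.testing.assert_frame_equal(a.disease_log_means, b.disease_log_means)

    def test_tpm_nonnegative_and_dimensions(self, small_compendium, small_config):
        assert small_compendium.n_genes == small_config.n_genes
        assert small_compendium.n_samples == small_config.n_samples
        assert (small_compendium.tpm.to_numpy() >= 0).all()
        assert set(small_compendium.metadata["disease"]) == {"D00", "D01", "D02"}

    def test_pediatric_fraction_within_binomial_ci(self):
        config = SimulationConfig(n_genes=50, n_samples=200, pediatric_fraction=0.164, seed=3)
        comp = generate_compendium(config)
        n_young = int((comp.metadata["age_at_diagnosis"] < 30).sum())
        lo, hi = binom.interval(0.95, 200, 0.164)
        assert lo <= n_young <= hi

    def test_zero_disease_shift_gives_one_shared_distribution(self):
        config = SimulationConfig(n_genes=40, n_samples=60, n_diseases=3, disease_shift_sd=0.0, seed=5)
        comp = generate_compendium(config)
        means = comp.disease_log_means
        for col in means.columns[1:]:
            assert np.allclose(means[col], means[means.columns[0]])

    def test_log_moments_converge_to_configured_values(self):
        # homogeneous compendium at n=1000: per-gene mean and sd of
        # log2(TPM+1) should sit within ~3 standard errors of the target
        config = SimulationConfig(
            n_genes=200, n_samples=1000, n_diseases=1, disease_shift_sd=0.0,
            baseline_log_mean=3.0, baseline_log_sd=0.8, seed=17,
        )
        comp = generate_compendium(config)
        L = log2_tpm(comp.tpm.to_numpy())
        se_mean = 0.8 / np.sqrt(1000)
        se_sd = 0.8 / np.sqrt(2 * 1000)
        frac_mean_ok = np.mean(np.abs(L.mean(axis=1) - 3.0) <= 3 * se_mean)
        frac_sd_ok = np.mean(np.abs(L.std(axis=1, ddof=1) - 0.8) <= 3 * se_sd)
        assert frac_mean_ok >= 0.98
        assert frac_sd_ok >= 0.98
        assert abs(L.mean() - 3.0) <= 4 * se_mean / np.sqrt(200)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_diseases": 10, "n_samples": 5},
            {"pediatric_fraction": 1.2},
            {"pediatric_fraction": -0.1},
            {"baseline_log_sd": -1.0},
            {"n_genes": 0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**kwargs)


class TestGenerateFocusSample:
    def test_determinism_and_ground_truth(self, small_compendium):
        a = generate_focus_sample(small_compendium, "D00", [("FLT3", 4.0)], seed=9)
        b = generate_focus_sample(small_compendium, "D00", [("FLT3", 4.0)], seed=9)
        pd.testing.assert_series_equal(a.tpm, b.tpm)
        assert a.truth_spikes == (("G00000", 4.0),)  # FLT3 heads the gene list

    def test_unknown_disease_or_gene_rejected(self, small_compendium):
        with pytest.raises(InputError):
            generate_focus_sample(small_compendium, "NOSUCH", seed=1)
        with pytest.raises(InputError):
            generate_focus_sample(small_compendium, "D00", [("NOSUCHGENE", 2.0)], seed=1)

    def test_null_sample_has_near_nominal_outlier_rate(self, small_compendium):
        # no spikes: an ordinary draw from its own disease; against the
        # same-disease cohort the per-gene outlier rate stays small
        rates = []
        members = small_compendium.metadata.index[small_compendium.metadata["disease"] == "D00"]
        cohort = type(small_compendium)(
            tpm=small_compendium.tpm[list(members)],
            genes=small_compendium.genes,
            metadata=small_compendium.metadata.loc[list(members)],
        )
        for seed in range(10):
            sample = generate_focus_sample(small_compendium, "D00", seed=seed)
            calls = call_outliers(sample, cohort, OutlierParams(), "pan_disease")
            rates.append(calls["is_outlier"].mean())
        assert np.mean(rates) < 0.02

    def test_zero_effect_spike_equals_null_distribution(self, small_compendium):
        spiked = generate_focus_sample(small_compendium, "D01", [("KIT", 0.0)], seed=4)
        plain = generate_focus_sample(small_compendium, "D01", seed=4)
        pd.testing.assert_series_equal(spiked.tpm, plain.tpm)


class TestGenerateDnaFindings:
    def test_neither_scenario_is_empty(self):
        scenario = generate_dna_findings([f"S{i}" for i in range(5)], "neither", seed=1)
        assert all(f == [] for f in scenario.findings.values())
        assert all(g == () for g in scenario.rna_actionable_genes.values())
        assert set(scenario.truth_cells.values()) == {"neither"}

    def test_both_scenario_always_actionable(self):
        scenario = generate_dna_findings([f"S{i}" for i in range(10)], "both", seed=2)
        for sid in scenario.findings:
            assert any(f.dna_actionable for f in scenario.findings[sid])
            assert scenario.rna_actionable_genes[sid]

    def test_mixed_scenario_cell_fractions_match_targets(self):
        ids = [f"S{i:04d}" for i in range(740)]
        scenario = generate_dna_findings(ids, "mixed", seed=6)
        cells = pd.Series(scenario.truth_cells)
        fractions = cells.value_counts(normalize=True)
        for cell, target in zip(("both", "dna_only", "rna_only", "neither"), MIXED_CELL_PROBS):
            assert abs(fractions[cell] - target) <= 0.03

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ConfigError):
            generate_dna_findings(["S1"], "sometimes", seed=0)
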