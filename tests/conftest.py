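import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from panoutlier.io import ExpressionCompendium
from panoutlier.simulate import (
    SimulationConfig,
    default_actionable_table,
    default_drug_table,
    generate_compendium,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_genes=300, n_samples=120, n_diseases=3, seed=11)


@pytest.fixture(scope="session")
def small_compendium(small_config) -> ExpressionCompendium:
    return generate_compendium(small_config)


@pytest.fixture(scope="session")
def actionable():
    return default_actionable_table()


@pytest.fixture(scope="session")
def drug_table():
    return default_drug_table()


def compendium_from_log(log_values: np.ndarray, gene_ids=None, sample_ids=None) -> ExpressionCompendium:
    """Build a compendium whose log2(TPM+1) values equal ``log_values`` exactly."""
    n_genes, n_samples = log_values.shape
    gene_ids = gene_ids or [f"G{i:03d}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"S{i:03d}" for i in range(n_samples)]
    tpm = np.exp2(np.asarray(log_values, dtype=float)) - 1.0
    genes = pd.DataFrame(
        {"symbol": [g.upper() for g in gene_ids], "in_filtered_universe": True},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    metadata = pd.DataFrame(
        {"disease": ["D"] * n_samples}, index=pd.Index(sample_ids, name="sample_id")
    )
    return ExpressionCompendium(
        tpm=pd.DataFrame(tpm, index=genes.index, columns=sample_ids),
        genes=genes,
        metadata=metadata,
    )
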