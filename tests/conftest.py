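"""Shared fixtures: small synthetic datasets generated at test time."""

import pandas as pd
import pytest

from omicsbridge import PipelineConfig, SimulationConfig, simulate_dataset


def small_config(**overrides) -> SimulationConfig:
    """A fast configuration: few genes, scaled-down libraries."""
    defaults = dict(
        n_genes=400,
        lib_sizes=(120000, 130000, 125000, 118000),
        n_qpcr_genes=10,
        seed=11,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def noise_free_config(**overrides) -> SimulationConfig:
    """Deterministic limit: no reporter/biological/count/Ct noise."""
    defaults = dict(
        sigma_reporter=0.0,
        sigma_bio=0.0,
        protein_jitter_sd=0.0,
        sigma_ct=0.0,
        exact_counts=True,
    )
    defaults.update(overrides)
    return small_config(**defaults)


@pytest.fixture(scope="session")
def small_dataset() -> dict[str, pd.DataFrame]:
    return simulate_dataset(small_config())


@pytest.fixture(scope="session")
def small_pipeline_config() -> PipelineConfig:
    return PipelineConfig(simulation=small_config())
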