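import numpy as np
import pandas as pd
import pytest

from thermomem.simulate import SimulationConfig, plant_truth, simulate_counts


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down study: 300 genes, 10 planted targets, 2 modules."""
    return SimulationConfig(
        n_genes=300,
        n_direct_targets=10,
        n_modules=2,
        module_sizes=(20, 20),
        n_ct_genes=30,
        n_ct_clusters=3,
        n_ct_undetectable=5,
        n_decoy_peaks=20,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return plant_truth(small_config)


@pytest.fixture(scope="session")
def small_counts(small_config, small_truth):
    counts, sheet = simulate_counts(small_config, small_truth)
    return counts, sheet
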