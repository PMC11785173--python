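import warnings

import numpy as np
import pytest

from traitgraph.synthetic import (
    SimulationConfig,
    simulate_burden_stats,
    simulate_cells,
    simulate_truth,
)

# sklearn NMF warns when max_iter is reached; irrelevant for consensus runs
warnings.filterwarnings("ignore", message="Maximum number of iterations")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Tiny but fully structured study used across module tests."""
    return SimulationConfig(
        n_genes=120,
        n_programs=2,
        n_regulators_per_program=5,
        n_member_genes_per_program=15,
        n_cells_per_perturbation=12,
        n_nontargeting_cells=200,
        mean_depth=1000,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_truth(small_config)


@pytest.fixture(scope="session")
def small_burden(small_truth, small_config):
    return simulate_burden_stats(small_truth, small_config, cohort_seed=1)


@pytest.fixture(scope="session")
def small_cells(small_truth, small_config):
    return simulate_cells(small_truth, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
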