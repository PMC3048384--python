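import numpy as np
import pytest

from causalflow.synthetic_data import SimulationConfig, simulate_cohort, worked_toy


@pytest.fixture(scope="session")
def toy():
    return worked_toy()


@pytest.fixture(scope="session")
def small_cohort():
    """One modest planted cohort shared by read-only tests."""
    config = SimulationConfig(
        n_tumor=80, n_control=20, n_genes=120, n_loci=24,
        n_planted_causal=2, seed=11,
    )
    expr, cnv, net, truth = simulate_cohort(config)
    return config, expr, cnv, net, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
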