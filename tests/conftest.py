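import numpy as np
import pytest

from stagesig import SimulationConfig, simulate_expression


@pytest.fixture(scope="session")
def default_sim():
    """One default-conditions simulation shared across tests (seed 0)."""
    expr, design, truth = simulate_expression(SimulationConfig(seed=0))
    return expr, design, truth


@pytest.fixture(scope="session")
def small_sim():
    """A fast small simulation: 300 genes, 10 planted."""
    cfg = SimulationConfig(n_genes=300, n_signature=10, seed=1)
    expr, design, truth = simulate_expression(cfg)
    return expr, design, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
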