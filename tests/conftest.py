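import numpy as np
import pytest

from noisenet import (
    NetworkGenotype,
    SimulationParams,
    WeightedDigraph,
    generate_topology,
)


@pytest.fixture
def two_gene_chain():
    """Gene 0 regulates gene 1 with weight 1; gene 0 is unregulated."""
    w = np.zeros((2, 2))
    w[1, 0] = 1.0
    return WeightedDigraph(w)


@pytest.fixture
def small_params():
    return SimulationParams(n_genes=2, n_pop=10, t_gen=5)


@pytest.fixture
def er_graph():
    return generate_topology("ER", 40, 0.05, seed=42)


@pytest.fixture
def default_params():
    return SimulationParams()
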