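import networkx as nx
import numpy as np
import pytest

from peerspread import DiffusionParams, NetworkSpec, generate_network


@pytest.fixture
def path3():
    g = nx.path_graph(3)
    nx.set_node_attributes(g, {0: "F", 1: "M", 2: "F"}, "gender")
    return g


@pytest.fixture
def star3():
    """Star with center 0 and three leaves."""
    g = nx.star_graph(3)
    nx.set_node_attributes(g, "M", "gender")
    return g


@pytest.fixture
def small_world():
    return generate_network(NetworkSpec(), seed=123)


@pytest.fixture
def no_reversion_params():
    return DiffusionParams(
        resistance_chance={"male": 0.0, "female": 0.0},
        reversion_mode="per_tick",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
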