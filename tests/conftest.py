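import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def k4_pendant() -> nx.Graph:
    """Complete graph on {1..4} plus pendant node 5 attached to vertex 1."""
    g = nx.complete_graph([1, 2, 3, 4])
    g.add_edge(1, 5)
    return g


@pytest.fixture(scope="session")
def planted_metabolomics():
    """Default planted three-group intensity matrix (seed 0) with its truth."""
    from herbnet.simulate import gen_metabolomics

    return gen_metabolomics(seed=0)


@pytest.fixture(scope="session")
def default_scenario():
    """Full default synthetic scenario (seed 0)."""
    from herbnet.simulate import gen_scenario

    return gen_scenario(seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
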