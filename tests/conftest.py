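import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

from herbnet import SimulationConfig, simulate_all

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def easy_config() -> SimulationConfig:
    """The documented default ('easy') simulation setting."""
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(easy_config):
    """One full synthetic input stack at the default setting."""
    return simulate_all(easy_config)


@pytest.fixture()
def path5() -> nx.Graph:
    """The 5-node path a-b-c-d-e used in the worked screening example."""
    g = nx.Graph()
    nx.add_path(g, list("abcde"))
    return g


def random_graph(seed: int, n: int | None = None, p: float | None = None) -> nx.Graph:
    """Seeded Erdos-Renyi graph with string node labels."""
    import random

    rng = random.Random(seed)
    n = n if n is not None else rng.randint(4, 50)
    p = p if p is not None else rng.uniform(0.05, 0.5)
    g = nx.gnp_random_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes()})
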