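import sys
from pathlib import Path

import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


def random_connected_graphs(n_graphs: int, max_nodes: int = 8, seed: int = 0):
    """Deterministic stream of small connected simple graphs."""
    import random

    rng = random.Random(seed)
    graphs = []
    while len(graphs) < n_graphs:
        n = rng.randint(3, max_nodes)
        p = rng.uniform(0.25, 0.9)
        g = nx.gnp_random_graph(n, p, seed=rng.randint(0, 2**31 - 1))
        if nx.is_connected(g):
            graphs.append(g)
    return graphs


@pytest.fixture
def triangle():
    return nx.complete_graph(3)


@pytest.fixture
def star5():
    """5-node star: hub 0, leaves 1-4."""
    return nx.star_graph(4)
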