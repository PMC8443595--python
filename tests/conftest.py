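import networkx as nx
import numpy as np
import pytest

from seednet.network import PPINetwork


@pytest.fixture
def toy_network() -> PPINetwork:
    """Path A-B-C-D plus pendant A-E: small enough to trace by hand."""
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("C", "D"), ("A", "E")])
    return PPINetwork(graph=g, provenance="toy")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)


def random_network(rng: np.random.Generator, max_nodes: int = 50) -> PPINetwork:
    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.02, 0.4))
    g = nx.fast_gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"G{i:03d}" for i in range(n)})
    return PPINetwork(graph=g, provenance="random")
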