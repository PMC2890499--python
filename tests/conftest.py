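import sys
from pathlib import Path

import networkx as nx
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper


@pytest.fixture
def two_k3_bridge() -> nx.Graph:
    """Two triangles joined by one bridge edge."""
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("A", "C"),
                      ("D", "E"), ("E", "F"), ("D", "F"), ("C", "D")])
    return g


@pytest.fixture
def two_k4_bridge() -> nx.Graph:
    """Two K4 cliques joined by one bridge edge; greedy Q optimum = 2 cliques."""
    g = nx.Graph()
    for grp in (["A1", "A2", "A3", "A4"], ["B1", "B2", "B3", "B4"]):
        for i in range(4):
            for j in range(i + 1, 4):
                g.add_edge(grp[i], grp[j])
    g.add_edge("A4", "B1")
    return g


def random_connected_graph(n: int, p: float, seed: int) -> nx.Graph:
    """Seeded G(n, p) conditioned on connectivity (re-draw until connected)."""
    for attempt in range(200):
        g = nx.gnp_random_graph(n, p, seed=seed * 1000 + attempt)
        if g.number_of_nodes() and nx.is_connected(g):
            return nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
    raise RuntimeError("could not draw a connected graph")
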