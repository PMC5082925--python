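"""Shared fixtures and oracle helpers.

networkx appears here and throughout the suite strictly as an
independent oracle: every quantity it checks is computed by cldnet's
own implementation first.
"""

from __future__ import annotations

import networkx as nx
import pytest
from hypothesis import settings

from cldnet.cld_io import CausalLink, CLDGraph, Variable
from cldnet.synthetic_data import cld_like, er_directed

settings.register_profile("suite", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("suite")


def make_graph(n: int, edges: list[tuple[int, int]]) -> CLDGraph:
    """Small literal graph over ids 1..n."""
    return CLDGraph([Variable(i, f"v{i:02d}") for i in range(1, n + 1)],
                    [CausalLink(s, t) for s, t in edges])


def to_networkx(g: CLDGraph) -> nx.DiGraph:
    G = nx.DiGraph()
    G.add_nodes_from(g.nodes())
    G.add_edges_from((l.source, l.target) for l in g.edges())
    return G


def random_graph(n: int, m: int, seed: int) -> CLDGraph:
    return er_directed(n, m, seed)


@pytest.fixture(scope="session")
def cld_graph() -> CLDGraph:
    """One deterministic study-scale synthetic CLD shared across tests."""
    return cld_like(seed=7)


@pytest.fixture()
def path_graph() -> CLDGraph:
    """Directed path 1 → 2 → 3 → 4."""
    return make_graph(4, [(1, 2), (2, 3), (3, 4)])


@pytest.fixture()
def three_cycle() -> CLDGraph:
    return make_graph(3, [(1, 2), (2, 3), (3, 1)])
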