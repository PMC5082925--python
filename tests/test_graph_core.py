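"""Degrees, BFS distances, path extraction and feedback-loop enumeration."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from cldnet.graph_core import (UNREACHABLE, bfs_distances, degrees,
                               find_feedback_loops, shortest_path)
from cldnet.synthetic_data import er_directed

from conftest import make_graph, to_networkx


def matrix_power_distance(g, source, target, kmax=None):
    """Independent oracle: d(s,t) = min k with (A^k)[s,t] > 0."""
    ids = g.nodes()
    pos = {v: i for i, v in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n), dtype=np.int64)
    for l in g.edges():
        A[pos[l.source], pos[l.target]] = 1
    if source == target:
        return 0
    P = np.eye(n, dtype=np.int64)
    for k in range(1, (kmax or n)):
        P = np.minimum(P @ A, 1)       # boolean reachability in exactly ≤ growing k
        if P[pos[source], pos[target]]:
            return k
    return None


class TestDegrees:
    def test_small_example(self):
        # A=1, B=2, C=3 with edges A→B, A→C, B→C
        g = make_graph(3, [(1, 2), (1, 3), (2, 3)])
        assert degrees(g) == {1: (0, 2), 2: (1, 1), 3: (2, 0)}

    @given(seed=st.integers(0, 10_000))
    def test_handshake_identity(self, seed):
        g = er_directed(20, 45, seed=seed)
        deg = degrees(g)
        assert sum(d[0] for d in deg.values()) == g.n_edges
        assert sum(d[1] for d in deg.values()) == g.n_edges

    @given(seed=st.integers(0, 10_000))
    def test_reversal_swaps_degree_maps(self, seed):
        g = er_directed(15, 30, seed=seed)
        rev = degrees(g.reversed())
        assert all(rev[v] == (dout, din) for v, (din, dout) in degrees(g).items())


class TestBfsDistances:
    def test_directed_path(self, path_graph):
        d = bfs_distances(path_graph, 1)
        assert d.finite() == {1: 0, 2: 1, 3: 2, 4: 3}
        back = bfs_distances(path_graph, 4)
        assert back.finite() == {4: 0}
        assert back[1] is UNREACHABLE

    def test_unknown_source(self, three_cycle):
        with pytest.raises(KeyError):
            bfs_distances(three_cycle, 99)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_matrix_power_oracle(self, seed):
        g = er_directed(30, 70, seed=seed)
        src = g.nodes()[seed % g.n_nodes]
        d = bfs_distances(g, src)
        for t in g.nodes():
            expect = 0 if t == src else matrix_power_distance(g, src, t)
            got = d[t]
            assert (got is UNREACHABLE and expect is None) or got == expect

    @given(seed=st.integers(0, 2_000))
    def test_triangle_inequality(self, seed):
        g = er_directed(12, 30, seed=seed)
        dist = {s: bfs_distances(g, s).finite() for s in g.nodes()}
        for a in g.nodes():
            for b, dab in dist[a].items():
                for c, dbc in dist[b].items():
                    if c in dist[a]:
                        assert dist[a][c] <= dab + dbc


class TestShortestPath:
    def test_simple_path(self, path_graph):
        assert shortest_path(path_graph, 1, 3) == [1, 2, 3]

    def test_unreachable(self, path_graph):
        assert shortest_path(path_graph, 4, 1) is UNREACHABLE

    def test_lexicographic_tie_break(self):
        # two equal paths 1→2→4 and 1→3→4: lower intermediate id wins
        g = make_graph(4, [(1, 2), (1, 3), (2, 4), (3, 4)])
        assert shortest_path(g, 1, 4) == [1, 2, 4]

    @pytest.mark.parametrize("seed", range(12))
    def test_valid_and_minimal_vs_exhaustive(self, seed):
        g = er_directed(20, 50, seed=seed)
        G = to_networkx(g)
        nodes = g.nodes()
        rng = np.random.default_rng(seed)
        for _ in range(10):
            s, t = rng.choice(nodes, size=2, replace=False)
            got = shortest_path(g, int(s), int(t))
            if not nx.has_path(G, s, t):
                assert got is UNREACHABLE
                continue
            paths = list(nx.all_shortest_paths(G, int(s), int(t)))
            assert got in paths                 # valid and minimal
            assert got == min(paths)            # lexicographically smallest


class TestFeedbackLoops:
    def test_single_three_cycle(self, three_cycle):
        loops = find_feedback_loops(three_cycle, 3)
        assert [lp.nodes for lp in loops] == [(1, 2, 3)]

    def test_dag_has_no_loops(self):
        g = er_directed(10, 20, seed=4)
        edges = [(l.source, l.target) for l in g.edges() if l.source < l.target]
        dag = make_graph(10, edges)
        assert find_feedback_loops(dag, 8) == []

    def test_through_filter(self):
        g = make_graph(5, [(1, 2), (2, 1), (3, 4), (4, 5), (5, 3)])
        loops = find_feedback_loops(g, 3, through=4)
        assert [lp.nodes for lp in loops] == [(3, 4, 5)]

    def test_cap_enforced_with_override(self, three_cycle):
        with pytest.raises(ValueError, match="cap"):
            find_feedback_loops(three_cycle, 9)
        assert find_feedback_loops(three_cycle, 9, cap=9)  # override accepted
        with pytest.raises(ValueError):
            find_feedback_loops(three_cycle, 1)

    @pytest.mark.parametrize("seed", range(25))
    def test_agrees_with_exhaustive_search_on_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        m = int(rng.integers(n, min(n * (n - 1), 3 * n) + 1))
        g = er_directed(n, m, seed=seed + 1000)
        got = {lp.nodes for lp in find_feedback_loops(g, max_length=7)}
        expected = set()
        for cyc in nx.simple_cycles(to_networkx(g)):
            if 2 <= len(cyc) <= 7:
                i = cyc.index(min(cyc))
                expected.add(tuple(cyc[i:] + cyc[:i]))
        assert got == expected

    def test_rotation_canonicalization(self):
        g = make_graph(4, [(2, 3), (3, 4), (4, 2)])
        (loop,) = find_feedback_loops(g, 3)
        assert loop.nodes[0] == min(loop.nodes)
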