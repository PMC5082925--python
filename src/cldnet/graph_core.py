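"""Directed-graph primitives: degrees, BFS shortest paths, feedback loops.

All distances follow edge direction strictly — a CLD's causal chains are
one-way — and are hop counts on the unweighted graph.  Unreachable pairs
are reported with an explicit :data:`UNREACHABLE` sentinel rather than a
large number, so downstream averages can never silently absorb
infinities.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterator, Union

from .cld_io import CLDGraph


class _Unreachable:
    """Sentinel for "no directed path exists"; never compared numerically."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNREACHABLE"

    def __bool__(self) -> bool:
        return False


UNREACHABLE = _Unreachable()

Distance = Union[int, _Unreachable]

#: Longest feedback loop enumerated by default.  Long causal chains in a
#: CLD are weak evidence (interference accumulates along them), and simple
#: -cycle enumeration is exponential in the length bound, so a low cap is
#: both the scientifically and computationally sane default.
DEFAULT_CYCLE_CAP = 8


@dataclass(frozen=True)
class DistanceResult:
    """Single-source directed hop distances with unreachable sentinel."""

    source: int
    distances: dict[int, Distance]

    def __getitem__(self, node: int) -> Distance:
        return self.distances[node]

    def finite(self) -> dict[int, int]:
        """Only the reachable nodes and their integer distances."""
        return {v: d for v, d in self.distances.items() if not isinstance(d, _Unreachable)}


@dataclass(frozen=True)
class FeedbackLoop:
    """A simple directed cycle, canonically rotated to start at its smallest id."""

    nodes: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.nodes)

    def __contains__(self, node: int) -> bool:
        return node in self.nodes


def degrees(g: CLDGraph) -> dict[int, tuple[int, int]]:
    """Per-variable (in_degree, out_degree); isolates report (0, 0)."""
    return {v: (len(g.predecessors(v)), len(g.successors(v))) for v in g.nodes()}


def bfs_distances(g: CLDGraph, source: int) -> DistanceResult:
    """Exact directed hop-count distances from ``source`` to every variable."""
    if not g.has_node(source):
        raise KeyError(f"unknown source id {source}")
    dist: dict[int, Distance] = {v: UNREACHABLE for v in g.nodes()}
    dist[source] = 0
    q: deque[int] = deque([source])
    while q:
        u = q.popleft()
        du = dist[u]
        assert isinstance(du, int)
        for v in g.successors(u):
            if isinstance(dist[v], _Unreachable):
                dist[v] = du + 1
                q.append(v)
    return DistanceResult(source, dist)


def shortest_path(g: CLDGraph, source: int,
                  target: int) -> Union[list[int], _Unreachable]:
    """One shortest directed path from source to target.

    Among all shortest paths the lexicographically smallest id sequence
    is returned, so the trace is deterministic.  Achieved by walking
    forward greedily: at each step take the smallest-id successor whose
    remaining distance to the target (computed by a backward BFS) still
    decreases by one.
    """
    for node in (source, target):
        if not g.has_node(node):
            raise KeyError(f"unknown id {node}")
    back = bfs_distances(g.reversed(), target).distances
    if isinstance(back[source], _Unreachable):
        return UNREACHABLE
    path = [source]
    current = source
    while current != target:
        remaining = back[current]
        assert isinstance(remaining, int)
        nxt = min(v for v in g.successors(current)
                  if isinstance(back[v], int) and back[v] == remaining - 1)
        path.append(nxt)
        current = nxt
    return path


def find_feedback_loops(g: CLDGraph, max_length: int,
                        through: int | None = None,
                        cap: int = DEFAULT_CYCLE_CAP) -> list[FeedbackLoop]:
    """All distinct simple directed cycles of length ≤ ``max_length``.

    Cycles are deduplicated by rotation (each starts at its smallest
    node id); direction is preserved, so a cycle and its reversal are
    distinct loops.  With ``through`` set, only loops containing that
    variable are returned.  ``max_length`` above ``cap`` raises — pass a
    larger ``cap`` explicitly to accept the exponential cost.
    """
    if max_length < 2:
        raise ValueError("max_length must be at least 2 (shortest directed cycle)")
    if max_length > cap:
        raise ValueError(
            f"max_length {max_length} exceeds the cycle-length cap {cap}; "
            f"pass cap={max_length} to override (enumeration cost grows exponentially)")
    if through is not None and not g.has_node(through):
        raise KeyError(f"unknown id {through}")
    loops: list[FeedbackLoop] = []
    # Each cycle is discovered exactly once, rooted at its smallest node:
    # DFS from each start s visiting only ids > s.
    for start in g.nodes():
        stack: list[tuple[int, list[int]]] = [(start, [start])]
        while stack:
            node, path = stack.pop()
            for nxt in reversed(g.successors(node)):
                if nxt == start and len(path) >= 2:
                    loops.append(FeedbackLoop(tuple(path)))
                elif nxt > start and nxt not in path and len(path) < max_length:
                    stack.append((nxt, path + [nxt]))
    if through is not None:
        loops = [lp for lp in loops if through in lp]
    return sorted(loops, key=lambda lp: (lp.length, lp.nodes))
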