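"""Modularity scoring and multi-level greedy (Louvain-style) communities.

Modularity Q measures how much more densely a partition's communities
are wired internally than a degree-matched random graph would be.  Two
variants are offered:

* ``undirected`` (default) — the graph is projected to a simple
  undirected graph (arc direction dropped, duplicate arcs merged) and

      Q = Σ_c [ e_c/m − (d_c / 2m)² ]

  with m undirected edges, e_c edges inside community c and d_c the
  total degree of c.  This is the projection the common desktop tools
  apply to a directed network by default, so it is the headline number.

* ``directed`` — arcs keep their direction and

      Q = Σ_c [ e_c/m − (K_c^out · K_c^in) / m² ]

  with m arcs and K^out/K^in the community out-/in-degree sums.

Internally one engine covers both: a symmetric arc set makes the
directed formula reduce exactly to the undirected one, so the
undirected variant is "symmetrize, then run the directed machinery".

The optimiser is the classic two-phase greedy: local moves (each node
repeatedly re-assigned to the neighbouring community with the largest
modularity gain) followed by aggregation of communities into
super-nodes, repeated until no gain remains.  Louvain is stochastic in
its node-visit order, so the search is restarted from independent
seeded shuffles and the best partition kept; with (seed, restarts)
fixed the result is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np

from .cld_io import CLDGraph

Variant = Literal["undirected", "directed"]


class EdgelessGraphError(ValueError):
    """Modularity is undefined on a graph with no edges."""


@dataclass(frozen=True)
class CommunityConfig:
    """Knobs for community detection used by report assembly."""

    seed: int = 0
    restarts: int = 20
    variant: Variant = "undirected"


@dataclass(frozen=True)
class Partition:
    """A community assignment together with its quality and provenance."""

    assignment: dict[int, int]
    n_communities: int
    modularity: float
    restarts: int
    seed: int
    variant: Variant

    def members(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for v, c in sorted(self.assignment.items()):
            out.setdefault(c, []).append(v)
        return out

    def to_json(self) -> str:
        meta = {"n_communities": self.n_communities,
                "modularity": self.modularity,
                "restarts": self.restarts, "seed": self.seed,
                "variant": self.variant,
                "assignment": {str(k): v for k, v in sorted(self.assignment.items())}}
        return json.dumps(meta, indent=2, sort_keys=True) + "\n"


def _arcs(g: CLDGraph, variant: Variant) -> list[tuple[int, int]]:
    arcs = [(l.source, l.target) for l in g.edges()]
    if variant == "undirected":
        und = {frozenset((s, t)) for s, t in arcs}
        arcs = []
        for pair in und:
            a, b = sorted(pair)
            arcs.extend([(a, b), (b, a)])
    elif variant != "directed":
        raise ValueError(f"unknown variant {variant!r}")
    return arcs


def modularity_score(g: CLDGraph, assignment: Mapping[int, int],
                     variant: Variant = "undirected") -> float:
    """Modularity Q of a complete assignment under the chosen variant."""
    missing = [v for v in g.nodes() if v not in assignment]
    if missing:
        raise ValueError(f"partial assignment: nodes {missing[:5]}... lack a community")
    arcs = _arcs(g, variant)
    if not arcs:
        raise EdgelessGraphError("modularity undefined on an edgeless graph")
    m = len(arcs)
    e_within: dict[int, int] = {}
    k_out: dict[int, int] = {}
    k_in: dict[int, int] = {}
    for s, t in arcs:
        cs, ct = assignment[s], assignment[t]
        k_out[cs] = k_out.get(cs, 0) + 1
        k_in[ct] = k_in.get(ct, 0) + 1
        if cs == ct:
            e_within[cs] = e_within.get(cs, 0) + 1
    q = 0.0
    for c in set(assignment.values()):
        q += e_within.get(c, 0) / m - (k_out.get(c, 0) * k_in.get(c, 0)) / m ** 2
    return q


class _Level:
    """Aggregated weighted directed graph for one Louvain level."""

    def __init__(self, nodes: list[int], arcs: list[tuple[int, int, float]]):
        self.nodes = nodes
        self.out_w: dict[int, dict[int, float]] = {v: {} for v in nodes}
        self.in_w: dict[int, dict[int, float]] = {v: {} for v in nodes}
        self.k_out: dict[int, float] = {v: 0.0 for v in nodes}
        self.k_in: dict[int, float] = {v: 0.0 for v in nodes}
        self.m = 0.0
        for s, t, w in arcs:
            self.out_w[s][t] = self.out_w[s].get(t, 0.0) + w
            self.in_w[t][s] = self.in_w[t].get(s, 0.0) + w
            self.k_out[s] += w
            self.k_in[t] += w
            self.m += w


def _local_moves(level: _Level, rng: np.random.Generator) -> dict[int, int]:
    """Phase 1: greedy node moves until no single move improves Q."""
    comm = {v: v for v in level.nodes}
    s_out = dict(level.k_out)   # Σ k_out over community members
    s_in = dict(level.k_in)
    m = level.m
    order = list(level.nodes)
    improved = True
    while improved:
        improved = False
        rng.shuffle(order)
        for v in order:
            c_old = comm[v]
            kvo, kvi = level.k_out[v], level.k_in[v]
            # arc weight between v and each neighbouring community
            # (both directions; self-loops stay with v and cancel out)
            link: dict[int, float] = {}
            for t, w in level.out_w[v].items():
                if t != v:
                    link[comm[t]] = link.get(comm[t], 0.0) + w
            for s, w in level.in_w[v].items():
                if s != v:
                    link[comm[s]] = link.get(comm[s], 0.0) + w
            # remove v from its community
            s_out[c_old] -= kvo
            s_in[c_old] -= kvi
            # gain of joining community c (relative to standing alone);
            # baseline is rejoining the old community
            best_c, best_gain = c_old, (link.get(c_old, 0.0) / m
                                        - (kvo * s_in[c_old] + kvi * s_out[c_old]) / m ** 2)
            for c in sorted(link):
                gain = link[c] / m - (kvo * s_in[c] + kvi * s_out[c]) / m ** 2
                if gain > best_gain + 1e-12 or (abs(gain - best_gain) <= 1e-12 and c < best_c):
                    best_c, best_gain = c, gain
            comm[v] = best_c
            s_out[best_c] += kvo
            s_in[best_c] += kvi
            if best_c != c_old:
                improved = True
    return comm


def _one_run(g_arcs: list[tuple[int, int, float]], nodes: list[int],
             rng: np.random.Generator) -> dict[int, int]:
    """One full multi-level Louvain pass; returns node → community."""
    mapping = {v: v for v in nodes}           # original node → current super-node
    level = _Level(nodes, g_arcs)
    while True:
        comm = _local_moves(level, rng)
        # relabel communities 0..k-1 by smallest member for determinism
        labels = sorted({c for c in comm.values()})
        relabel = {c: i for i, c in enumerate(labels)}
        comm = {v: relabel[c] for v, c in comm.items()}
        n_comms = len(labels)
        mapping = {v: comm[mapping[v]] for v in mapping}
        if n_comms == len(level.nodes):       # no aggregation progress
            break
        # Phase 2: aggregate
        agg: dict[tuple[int, int], float] = {}
        for s in level.nodes:
            for t, w in level.out_w[s].items():
                key = (comm[s], comm[t])
                agg[key] = agg.get(key, 0.0) + w
        level = _Level(list(range(n_comms)), [(s, t, w) for (s, t), w in agg.items()])
    return mapping


def louvain(g: CLDGraph, seed: int = 0, restarts: int = 20,
            variant: Variant = "undirected") -> Partition:
    """Best-of-restarts Louvain community detection.

    Each restart shuffles node visitation with an independent stream
    derived from (seed, restart index); ties in modularity gain break
    toward the lower community label.  The returned partition's Q is
    recomputed with :func:`modularity_score`, so the two always agree
    exactly.
    """
    if g.n_edges < 1:
        raise EdgelessGraphError("community detection needs at least one edge")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    arcs = [(s, t, 1.0) for s, t in _arcs(g, variant)]
    nodes = g.nodes()
    best: tuple[float, dict[int, int]] | None = None
    for r in range(restarts):
        rng = np.random.default_rng([seed, r])
        assignment = _one_run(arcs, nodes, rng)
        q = modularity_score(g, assignment, variant)
        if best is None or q > best[0] + 1e-15:
            best = (q, assignment)
    assert best is not None
    q, assignment = best
    # canonical labels: communities numbered by their smallest member id
    order = sorted({c: min(v for v in assignment if assignment[v] == c)
                    for c in set(assignment.values())}.items(), key=lambda kv: kv[1])
    relabel = {c: i for i, (c, _) in enumerate(order)}
    assignment = {v: relabel[c] for v, c in sorted(assignment.items())}
    # recompute on the canonical labels so the stored Q is bit-identical
    # to modularity_score(assignment) (summation order matters at 1e-16)
    q = modularity_score(g, assignment, variant)
    return Partition(assignment=assignment, n_communities=len(relabel),
                     modularity=q, restarts=restarts, seed=seed, variant=variant)
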