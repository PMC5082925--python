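"""Whole-network structural summaries for a causal loop diagram.

These are the map-level quantities a facilitator reads off before
looking at any single variable: how saturated the map is with causal
links (density), how causal involvement is spread over variables (degree
distributions), how many steps change typically needs to propagate
(average path length), the longest minimum causal chain (diameter), and
how cluster-divided the map is (modularity, delegated to
:mod:`cldnet.community`).

Average path length uses the reachable-ordered-pairs convention: the
mean is taken over ordered pairs (i, j), i ≠ j, for which a directed
path exists, and unreachable pairs are excluded from both numerator and
denominator.  On a sparse directed map with isolates this is the only
convention that yields a finite, interpretable number; it matches the
behaviour of the common desktop network-analysis tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal, Optional, TYPE_CHECKING

from .cld_io import CLDGraph
from .graph_core import bfs_distances, degrees

if TYPE_CHECKING:  # pragma: no cover
    from .community import CommunityConfig


class UndefinedMetricError(ValueError):
    """Raised when a metric has no value on the given graph."""


@dataclass(frozen=True)
class DegreeDistribution:
    """Exact histogram of in- or out-degree over all variables."""

    direction: Literal["in", "out"]
    histogram: dict[int, int]
    min: int
    max: int

    @property
    def n_nodes(self) -> int:
        return sum(self.histogram.values())


@dataclass
class GlobalReport:
    """One CLD's structural summary row.

    ``modularity`` is filled by community detection when a community
    configuration is supplied to :func:`global_report`, else ``None``.
    """

    n_nodes: int
    n_edges: int
    density: float
    avg_path_length: float
    diameter: int
    diameter_endpoints: tuple[int, int]
    n_isolates: int
    n_reachable_pairs: int
    modularity: Optional[float] = None

    def rounded(self) -> dict:
        """Report-ready dict: density 3 d.p., path length 2 d.p., Q 2 d.p.

        Internal values keep full precision; rounding happens only here,
        at serialization time.
        """
        d = asdict(self)
        d["density"] = round(self.density, 3)
        d["avg_path_length"] = round(self.avg_path_length, 2)
        if self.modularity is not None:
            d["modularity"] = round(self.modularity, 2)
        d["diameter_endpoints"] = list(self.diameter_endpoints)
        return d

    def to_json(self) -> str:
        return json.dumps(self.rounded(), indent=2, sort_keys=True) + "\n"

    def to_csv_row(self) -> str:
        """One-row CSV in the conventional summary-table column order."""
        d = self.rounded()
        cols = ["n_nodes", "n_edges", "density", "avg_path_length", "modularity",
                "diameter", "n_isolates", "n_reachable_pairs"]
        header = ",".join(cols)
        q = "" if d["modularity"] is None else d["modularity"]
        row = ",".join(str(x) for x in
                       [d["n_nodes"], d["n_edges"], d["density"], d["avg_path_length"],
                        q, d["diameter"], d["n_isolates"], d["n_reachable_pairs"]])
        return header + "\n" + row + "\n"


def density(g: CLDGraph) -> float:
    """E / (N·(N−1)): realised fraction of possible directed links.

    Isolates count toward N — an identified variable with no causal links
    still enlarges the space of links the group could have drawn.
    """
    n = g.n_nodes
    if n < 2:
        raise UndefinedMetricError("density undefined for a single-variable graph")
    return g.n_edges / (n * (n - 1))


def degree_distribution(g: CLDGraph, direction: Literal["in", "out"]) -> DegreeDistribution:
    """Exact degree histogram in the chosen direction."""
    if direction not in ("in", "out"):
        raise ValueError(f"direction must be 'in' or 'out', got {direction!r}")
    idx = 0 if direction == "in" else 1
    values = [dd[idx] for dd in degrees(g).values()]
    hist: dict[int, int] = {}
    for v in values:
        hist[v] = hist.get(v, 0) + 1
    return DegreeDistribution(direction, dict(sorted(hist.items())), min(values), max(values))


def _all_pairs_finite(g: CLDGraph):
    """Yield (source, target, distance) over reachable ordered pairs, i ≠ j."""
    for s in g.nodes():
        for t, d in bfs_distances(g, s).finite().items():
            if t != s:
                yield s, t, d


def average_path_length(g: CLDGraph) -> tuple[float, int]:
    """Mean directed shortest-path length over reachable ordered pairs.

    Returns (mean, number of reachable ordered pairs).  Raises if no
    ordered pair is connected at all.
    """
    total = 0
    count = 0
    for _, _, d in _all_pairs_finite(g):
        total += d
        count += 1
    if count == 0:
        raise UndefinedMetricError("no reachable ordered pair: average path length undefined")
    return total / count, count


def diameter(g: CLDGraph) -> tuple[int, tuple[int, int]]:
    """Maximum finite directed shortest-path length and one achieving pair.

    Ties are broken toward the smallest (source, target) id pair so the
    reported endpoints are deterministic.
    """
    best = -1
    best_pair: tuple[int, int] | None = None
    for s, t, d in _all_pairs_finite(g):
        if d > best or (d == best and best_pair is not None and (s, t) < best_pair):
            best, best_pair = d, (s, t)
    if best_pair is None:
        raise UndefinedMetricError("no reachable ordered pair: diameter undefined")
    return best, best_pair


def global_report(g: CLDGraph,
                  community_config: "CommunityConfig | None" = None) -> GlobalReport:
    """Assemble the full structural summary for one CLD.

    Every field equals the corresponding standalone operation; this is a
    convenience assembly, not a separate computation path.
    """
    apl, n_pairs = average_path_length(g)
    diam, endpoints = diameter(g)
    q: Optional[float] = None
    if community_config is not None:
        from .community import louvain
        q = louvain(g, seed=community_config.seed, restarts=community_config.restarts,
                    variant=community_config.variant).modularity
    return GlobalReport(
        n_nodes=g.n_nodes,
        n_edges=g.n_edges,
        density=density(g),
        avg_path_length=apl,
        diameter=diam,
        diameter_endpoints=endpoints,
        n_isolates=len(g.isolates()),
        n_reachable_pairs=n_pairs,
        modularity=q,
    )
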