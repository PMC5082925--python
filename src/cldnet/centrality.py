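"""Node-importance measures and leverage-point views for a CLD.

Three complementary readings of a variable's position:

* **in-degree** — how many direct causes act on it (an "effect hub");
* **out-degree** — how many variables it directly drives (a "cause hub");
* **betweenness** — how often it sits on shortest causal chains between
  other variables (a "mediator" brokering the spread of change across
  the map).

Betweenness is the directed, unweighted Brandes accumulation

    C_B(v) = Σ_{s≠v≠t, σ_st>0}  σ_st(v) / σ_st

over ordered pairs, endpoints excluded, *unnormalized* by default: on a
map of ~100 variables the raw counts (hundreds) are the scale
practitioners quote.  ``normalized=True`` divides by (N−1)(N−2).
"""

from __future__ import annotations

from collections import deque

import pandas as pd

from .cld_io import CLDGraph
from .graph_core import degrees


def betweenness(g: CLDGraph, normalized: bool = False) -> dict[int, float]:
    """Brandes betweenness centrality on the directed unweighted graph.

    One BFS per source builds the shortest-path DAG (path counts σ and
    predecessor lists), then dependencies are accumulated in reverse
    order of distance:  δ(v) = Σ_{w: v ∈ pred(w)} σ_v/σ_w · (1 + δ(w)).
    Runs in O(N·E); exact for every node, isolates score 0.
    """
    cb: dict[int, float] = {v: 0.0 for v in g.nodes()}
    for s in g.nodes():
        # single-source shortest-path DAG
        sigma: dict[int, float] = {v: 0.0 for v in cb}
        dist: dict[int, int] = {}
        preds: dict[int, list[int]] = {v: [] for v in cb}
        sigma[s] = 1.0
        dist[s] = 0
        order: list[int] = []
        q: deque[int] = deque([s])
        while q:
            u = q.popleft()
            order.append(u)
            for w in g.successors(u):
                if w not in dist:
                    dist[w] = dist[u] + 1
                    q.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
                    preds[w].append(u)
        # dependency accumulation, farthest first
        delta: dict[int, float] = {v: 0.0 for v in order}
        for w in reversed(order):
            for u in preds[w]:
                delta[u] += sigma[u] / sigma[w] * (1.0 + delta[w])
            if w != s:
                cb[w] += delta[w]
    if normalized:
        n = g.n_nodes
        scale = (n - 1) * (n - 2)
        if scale > 0:
            cb = {v: c / scale for v, c in cb.items()}
    return cb


def centrality_table(g: CLDGraph) -> pd.DataFrame:
    """Per-variable centrality measures with dense ranks.

    Columns: id (index), name, in_degree, out_degree, betweenness, and a
    ``<measure>_rank`` for each (rank 1 = largest value; ties share a
    dense rank).  Rows are ordered by ascending id so output is
    deterministic; within a shared rank the id order is the tie-break
    for any top-k listing derived from the table.
    """
    deg = degrees(g)
    cb = betweenness(g)
    ids = g.nodes()
    df = pd.DataFrame({
        "name": [g.name(v) for v in ids],
        "in_degree": [deg[v][0] for v in ids],
        "out_degree": [deg[v][1] for v in ids],
        "betweenness": [cb[v] for v in ids],
    }, index=pd.Index(ids, name="id"))
    for col in ("in_degree", "out_degree", "betweenness"):
        df[f"{col}_rank"] = df[col].rank(method="dense", ascending=False).astype(int)
    return df


def top_ranked(table: pd.DataFrame, measure: str, k: int = 10) -> list[int]:
    """Top-k variable ids by a measure, ties broken by ascending id.

    Relies on the table being id-ordered and the sort being stable.
    """
    ordered = table.sort_index().sort_values(measure, ascending=False, kind="mergesort")
    return ordered.head(k).index.tolist()


def root_influencers(g: CLDGraph, min_out: int = 1) -> list[int]:
    """Variables with in-degree 0 and out-degree ≥ min_out.

    These drive parts of the system while nothing in the mapped system
    drives them — the community has identified no lever over them, which
    makes them either exogenous forces or blind spots in the map.
    Sorted by descending out-degree, then ascending id.
    """
    if min_out < 1:
        raise ValueError("min_out must be at least 1")
    deg = degrees(g)
    hits = [v for v, (din, dout) in deg.items() if din == 0 and dout >= min_out]
    return sorted(hits, key=lambda v: (-deg[v][1], v))
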