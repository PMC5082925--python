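# Methods

## The model of a causal loop diagram

A CLD is modelled as a simple directed unweighted graph: variables are
nodes identified by positive integer ids with human-readable names,
causal relationships are arcs x_ij ∈ {0,1}. Self-loops are rejected at
parse time — a variable "causing itself" has no meaning at the grain of
a CLD and would corrupt the N(N−1) density denominator — and duplicate
arcs are collapsed with a warning, since the network is unweighted.
Link polarity (positive/negative) is parsed and stored but ignored by
every metric; polarity-aware analysis is a deliberate non-goal of this
package's scope. The node universe is the union of the variable key and
the edge endpoints: the key is authoritative for names, endpoints
missing from it are added as `unlabelled-<id>` with a warning, and
degree-0 variables (isolates) are retained — an identified variable
with no links is information, not noise.

## Path-based quantities

All distances follow arc direction strictly and count hops (BFS on the
unweighted digraph). Unreachable pairs carry an explicit sentinel, never
a large number, so no average can silently absorb an infinity.

**Average path length** is the mean over *reachable ordered pairs*
(i ≠ j); unreachable pairs are excluded from numerator and denominator.
On a sparse directed map with isolates this is the only convention that
yields a finite, interpretable value, and it matches the default
behaviour of the desktop network tools practitioners use. This
convention choice is worth flagging: with any penalised-infinity
convention the same map produces very different numbers.

**Diameter** is the maximum finite directed distance; ties in the
achieving pair break toward the smallest (source, target) ids.
**Path extraction** returns the lexicographically smallest id sequence
among shortest paths (greedy forward walk guided by a backward BFS), so
reported causal chains are deterministic.

**Betweenness** is Brandes' O(NE) accumulation on the directed graph,
endpoints excluded, *unnormalized* by default: on a ~100-variable map
the raw counts (hundreds) are the scale practitioners quote, and the
normalized variant (÷ (N−1)(N−2)) is available as a flag.

**Feedback loops** are simple directed cycles enumerated by DFS rooted
at each cycle's smallest node id (rotation-canonical, direction
preserved), bounded by a default length cap of 8: long causal chains in
a CLD are weak evidence, and enumeration is exponential in the bound.
The cap is overridable explicitly.

## Communities and modularity

Two modularity variants are exposed. The default projects the digraph
to a simple undirected graph and scores Q = Σ_c [e_c/m − (d_c/2m)²];
the directed variant keeps arcs and scores
Q = Σ_c [e_c/m − K_c^out·K_c^in / m²]. Internally one directed engine
serves both, because on a symmetrized arc set the directed formula
reduces algebraically to the undirected one (verified in the tests on
disjoint 3-cycles, where both give exactly 0.5).

The optimiser is classic two-phase Louvain (greedy local moves, then
aggregation, repeated to a fixed point) with resolution fixed at 1.0.
Louvain is stochastic in its node-visit order; the search restarts from
independent seeded shuffles (default 20) and keeps the best partition.
Ties in move gain break toward the lower community label; community
labels are canonicalised by smallest member id; the reported Q is
recomputed from the final assignment so it is bit-identical to
`modularity_score`. Determinism contract: same (graph, seed, restarts,
variant) → same partition. The best-of-restarts Q is monotone in the
number of restarts under the same seed sequence, and the analysis
scripts report the restart trajectory so the stochastic spread is
visible rather than hidden.

## Random baselines and topology classification

Qualitative labels — "small-world-like", "scale-free-like" — are made
quantitative by comparing the observed map with an ensemble of uniform
directed G(N, E) graphs at matched size (default 20 replicates, all
seeded). For average path length, diameter, modularity and the two
degree maxima the module reports z = (obs − mean)/sd, with z undefined
(reported as null) where the ensemble is degenerate (sd = 0). The
uniform null is deliberate: a degree-preserving rewiring null would
build the observed hubs into the baseline and erase the heavy-tail
signal being tested. The heavy-tail call — observed max degree more
than 3 ensemble standard deviations above the ensemble mean — is a
declared convention of this package, not a statistical test with
calibrated error rates, and no power-law exponent is fitted: with
degree maxima in the low teens an exponent estimate would be
unsupportable.

## The synthetic map generator

`cld_like` emulates the statistical structure of a real community
systems map at the 114-variable / 209-link scale: exactly one isolate,
five planted thematic clusters, a dominant "outcome" hub collecting 14
causes, a top "driver" emitting 7 effects, a planted 3-cycle, and every
other variable involved in at least one link. Filler links are drawn
half within clusters and with degree-preferential endpoints (capped at
the hub maxima); the preferential filler is what gives the map hub
shortcuts, so its average path length (≈4.7–4.9 across seeds) comes out
*below* the matched uniform baseline (≈6.2), as in real maps, while
modularity lands at ≈0.56 ± 0.03. These defaults were set by matching
the generator's output distribution to that target profile across seeds
0–7 before the test suite was finalised.

What the generator does **not** emulate: real variable names and their
semantics, polarity structure, the social process that produces
correlated motifs (chains of intermediate variables along workshop
narratives), or any particular map's exact degree sequence. Tests that
pass on `cld_like` therefore demonstrate algorithmic correctness and
robustness at realistic scale and structure — not agreement with any
specific published map, which requires that map's own key and edge
list (see `tests/test_acceptance.py`).

`er_directed` samples uniform G(n, m) without replacement (exact edge
count); `preferential_attachment_directed` grows the graph by arrival
order with target choice ∝ (in-degree + 1) — the +1 keeps fresh nodes
reachable; `ring_rewire` is a directed lattice-plus-rewiring
small-world generator. Every generator is a pure function of
(parameters, seed); auto-generated names embed kind and seed so
independently generated maps have disjoint name spaces unless aligned
via `name_prefix`.

## Numerical and reporting conventions

- Internal values keep full precision; rounding happens only at
  serialization (density 3 d.p., path length 2 d.p., betweenness 1
  d.p., modularity 2 d.p.).
- Ranks are dense (ties share a rank), secondary order by ascending id.
- Every stochastic operation takes an explicit seed; there is no hidden
  global random state. Streams are derived per purpose via
  `numpy.random.default_rng([seed, tag, index])`, so stages never share
  or consume each other's randomness.
- Comparison matches variables by normalised name (lowercase,
  punctuation stripped, whitespace collapsed); synonym matching is out
  of scope. With more than two bundles the rank correlations are
  reported for the first pair.
- Problem sizes used by the scripted analyses and the acceptance
  script: one 114-node map, 20 Louvain restarts, 20 baseline
  replicates, loop cap 4 — the full pipeline completes in a few seconds
  on one core.

## Known limitations

- Louvain is a greedy heuristic: on adversarial small graphs it can
  miss the optimal partition (the suite checks it stays within 0.05 of
  the exhaustive optimum on ≤8-node instances, not that it attains it).
- Cycle enumeration is exponential in the length cap; the cap exists
  for interpretability as much as cost, and counts above ~8 should not
  be read as meaningful anyway.
- The heavy-tail rule is a screening convention; it says "far outside
  uniform randomness", not "power-law distributed".
- Graph comparison is name-based and fails loudly at zero overlap;
  maps built with different vocabularies need upstream harmonisation.
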