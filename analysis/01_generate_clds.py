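#!/usr/bin/env python
"""Generate the two synthetic community systems maps used downstream.

Writes a primary study-scale causal loop diagram (114 variables, 209
links, one isolate, planted hubs/clusters/feedback loop) and a second
map from an independent seed with an aligned variable-name space, so
the cross-map comparison step has something real to match on.
"""

from pathlib import Path

from cldnet.cld_io import export_graph, export_variable_key
from cldnet.synthetic_data import cld_like

OUT = Path(__file__).resolve().parents[1] / "results" / "data"

for label, seed in (("map_a", 7), ("map_b", 8)):
    g = cld_like(seed=seed, name_prefix="community-var")
    d = OUT / label
    d.mkdir(parents=True, exist_ok=True)
    (d / "key.csv").write_text(export_variable_key(g))
    (d / "edges.csv").write_text(export_graph(g, "edge-csv"))
    print(f"{label}: seed={seed}  N={g.n_nodes}  E={g.n_edges}  "
          f"isolates={g.isolates()}  -> {d}")
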