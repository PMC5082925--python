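#!/usr/bin/env python
"""Leverage points of the primary map: hubs, mediators, root influencers.

Ranks every variable by in-degree (effect hubs), out-degree (cause
hubs) and unnormalized directed betweenness (mediators brokering
shortest causal chains), and lists the root influencers — variables
with in-degree zero that nothing in the mapped system can change.
"""

import json
from pathlib import Path

from cldnet.centrality import centrality_table, root_influencers, top_ranked
from cldnet.cld_io import read_cld

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data" / "map_a"

g = read_cld(DATA / "key.csv", DATA / "edges.csv")
table = centrality_table(g)
table.round({"betweenness": 1}).to_csv(ROOT / "centrality.csv")

views = {
    "effect_hubs_top5": top_ranked(table, "in_degree", 5),
    "cause_hubs_top5": top_ranked(table, "out_degree", 5),
    "mediators_top5": top_ranked(table, "betweenness", 5),
    "root_influencers": root_influencers(g, min_out=2),
}
(ROOT / "leverage_points.json").write_text(json.dumps(views, indent=2) + "\n")

for label, ids in views.items():
    rows = [f"{v} ({g.name(v)})" for v in ids[:5]]
    print(f"{label}: {', '.join(rows)}")
print("High-betweenness mediators are the candidate leverage points: "
      "change must traverse them to spill across clusters.")
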