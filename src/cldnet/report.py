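"""End-to-end analysis bundles and cross-CLD comparison.

``analyze`` runs the whole pipeline on one CLD — structural summary,
centrality table, community partition, optional random-baseline
comparison and feedback-loop census — and can write the results to an
output directory as JSON/CSV.  The bundle records full provenance
(input paths and hashes, configuration, seeds, package version), so a
re-run on identical inputs is byte-identical; no timestamps enter any
payload.

``compare`` puts two or more bundles side by side: global metric rows
and deltas, plus Spearman rank correlations of the centrality measures
over variables matched by normalised name (lowercase, punctuation
stripped, whitespace collapsed).  Name matching is deliberately dumb —
synonym detection belongs to a human, not this module.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .centrality import centrality_table
from .cld_io import CLDGraph, Dialect, read_cld
from .community import CommunityConfig, Partition, louvain
from .global_metrics import GlobalReport, global_report
from .graph_core import FeedbackLoop, find_feedback_loops
from .topology_baselines import BaselineComparison, compare_to_random


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything that parameterises one end-to-end run."""

    seed: int = 0
    restarts: int = 20
    variant: str = "undirected"
    baseline_replicates: int = 0        # 0 = skip the random-ensemble stage
    loops_max_length: int = 0           # 0 = skip loop enumeration
    delimiter: str = ","
    header: bool = True
    polarity_column: Optional[str] = None

    def dialect(self) -> Dialect:
        return Dialect(delimiter=self.delimiter, header=self.header)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class AnalysisBundle:
    """Every artefact of one CLD analysis plus the provenance to re-run it."""

    graph: CLDGraph
    global_report: GlobalReport
    centrality: pd.DataFrame
    partition: Partition
    baseline: Optional[BaselineComparison]
    loops: Optional[list[FeedbackLoop]]
    provenance: dict = field(default_factory=dict)

    def variable_names(self) -> dict[int, str]:
        return dict(self.graph.names())

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "global.json").write_text(self.global_report.to_json())
        (out / "global.csv").write_text(self.global_report.to_csv_row())
        self.centrality.round({"betweenness": 1}).to_csv(out / "centrality.csv")
        (out / "partition.json").write_text(self.partition.to_json())
        part_rows = pd.DataFrame({
            "id": sorted(self.partition.assignment),
            "name": [self.graph.name(v) for v in sorted(self.partition.assignment)],
            "community": [self.partition.assignment[v]
                          for v in sorted(self.partition.assignment)],
        })
        part_rows.to_csv(out / "partition.csv", index=False)
        if self.baseline is not None:
            (out / "baseline.json").write_text(self.baseline.to_json())
        if self.loops is not None:
            (out / "loops.json").write_text(json.dumps(
                [list(lp.nodes) for lp in self.loops], indent=2) + "\n")
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True) + "\n")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def analyze(key_path: str | Path, edges_path: str | Path,
            config: AnalysisConfig = AnalysisConfig(),
            out_dir: str | Path | None = None) -> AnalysisBundle:
    """Run the full pipeline on one CLD given as key + edge-list files."""
    g = read_cld(key_path, edges_path, config.dialect(), config.polarity_column)
    return analyze_graph(g, config,
                         provenance_inputs={
                             "key_path": str(key_path), "key_sha256": _sha256(key_path),
                             "edges_path": str(edges_path), "edges_sha256": _sha256(edges_path),
                         },
                         out_dir=out_dir)


def analyze_graph(g: CLDGraph, config: AnalysisConfig = AnalysisConfig(),
                  provenance_inputs: dict | None = None,
                  out_dir: str | Path | None = None) -> AnalysisBundle:
    """Pipeline entry point when the graph is already in memory."""
    cc = CommunityConfig(seed=config.seed, restarts=config.restarts,
                         variant=config.variant)  # type: ignore[arg-type]
    rep = global_report(g, cc)
    part = louvain(g, seed=config.seed, restarts=config.restarts,
                   variant=config.variant)  # type: ignore[arg-type]
    table = centrality_table(g)
    baseline = (compare_to_random(g, config.baseline_replicates, seed=config.seed)
                if config.baseline_replicates else None)
    loops = (find_feedback_loops(g, config.loops_max_length)
             if config.loops_max_length else None)
    provenance = {
        "inputs": provenance_inputs or {},
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
        "version": __version__,
    }
    bundle = AnalysisBundle(graph=g, global_report=rep, centrality=table,
                            partition=part, baseline=baseline, loops=loops,
                            provenance=provenance)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


# ---------------------------------------------------------------------------
# cross-CLD comparison
# ---------------------------------------------------------------------------

_PUNCT = re.compile(r"[^\w\s]")


def normalize_name(name: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace."""
    return re.sub(r"\s+", " ", _PUNCT.sub(" ", name.lower())).strip()


@dataclass
class ComparisonReport:
    """Side-by-side structural metrics and centrality rank agreement."""

    global_rows: pd.DataFrame               # one row per CLD
    deltas: pd.DataFrame                    # each CLD minus the first
    rank_correlations: dict[str, float]     # Spearman rho per measure
    n_matched: int
    matched_names: list[str]
    unmatched: list[list[str]]              # per bundle, names with no global match

    def to_json(self) -> str:
        return json.dumps({
            "global_rows": self.global_rows.to_dict(orient="records"),
            "deltas": self.deltas.to_dict(orient="records"),
            "rank_correlations": self.rank_correlations,
            "n_matched": self.n_matched,
            "matched_names": self.matched_names,
            "unmatched": self.unmatched,
        }, indent=2, sort_keys=True) + "\n"


def compare(bundles: Sequence[AnalysisBundle],
            labels: Sequence[str] | None = None) -> ComparisonReport:
    """Compare ≥ 2 analysis bundles over name-matched variables.

    Spearman rank correlations (average ranks on ties) are computed for
    in-degree, out-degree and betweenness between the first bundle and
    each other bundle over the variables present in *all* bundles after
    name normalisation; with more than two bundles the reported rho per
    measure is against the second bundle (pairwise extension is a
    caller-side loop).
    """
    if len(bundles) < 2:
        raise ValueError("need at least two bundles to compare")
    labels = list(labels) if labels is not None else [f"cld_{i}" for i in range(len(bundles))]
    name_maps = [{normalize_name(n): v for v, n in b.variable_names().items()}
                 for b in bundles]
    shared = set(name_maps[0])
    for nm in name_maps[1:]:
        shared &= set(nm)
    if not shared:
        raise ValueError("no variables matched by name across the given CLDs")
    matched = sorted(shared)
    unmatched = [sorted(set(nm) - shared) for nm in name_maps]

    rows = []
    for label, b in zip(labels, bundles):
        row = {"cld": label, **b.global_report.rounded()}
        row.pop("diameter_endpoints")
        rows.append(row)
    global_rows = pd.DataFrame(rows)
    numeric = global_rows.drop(columns=["cld"]).astype(float)
    deltas = numeric.subtract(numeric.iloc[0], axis=1)
    deltas.insert(0, "cld", labels)

    rho: dict[str, float] = {}
    ref_ids = [name_maps[0][n] for n in matched]
    oth_ids = [name_maps[1][n] for n in matched]
    for measure in ("in_degree", "out_degree", "betweenness"):
        a = bundles[0].centrality.loc[ref_ids, measure].to_numpy(dtype=float)
        b = bundles[1].centrality.loc[oth_ids, measure].to_numpy(dtype=float)
        if len(a) < 2 or (a == a[0]).all() or (b == b[0]).all():
            rho[measure] = float("nan")
        else:
            rho[measure] = float(stats.spearmanr(a, b).statistic)
    return ComparisonReport(global_rows=global_rows, deltas=deltas,
                            rank_correlations=rho, n_matched=len(matched),
                            matched_names=matched, unmatched=unmatched)
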