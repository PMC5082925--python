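"""Random-ensemble baselines for topology classification of a CLD.

A systems map is often described qualitatively as "small-world-like"
(sparse yet short average paths) or "scale-free-like" (heavy-tailed
degrees dominated by hubs).  This module turns those adjectives into
numbers: the observed map is compared against an ensemble of uniform
directed G(N, E) random graphs with matched node and edge counts, and
each metric is reported as a z-score

    z = (observed − ensemble mean) / ensemble sd.

The uniform baseline is deliberate: the question is how far the map
deviates from structureless randomness at the same size and sparsity.
A degree-preserving rewiring null would build the hubs into the
baseline and erase exactly the heavy-tail signal being tested.

The heavy-tail call uses a declared 3-sigma convention: a direction's
degree maximum is flagged heavy-tailed when it exceeds the ensemble
mean by more than three ensemble standard deviations.  There is no
power-law exponent fit — with degree maxima in the low teens any
exponent estimate would be unsupportable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .cld_io import CLDGraph
from .community import louvain
from .global_metrics import (UndefinedMetricError, average_path_length,
                             degree_distribution, diameter)
from .synthetic_data import er_directed

logger = logging.getLogger("cldnet")

_METRICS = ("avg_path_length", "diameter", "modularity", "max_in_degree", "max_out_degree")

#: Louvain restarts per ensemble replicate — each replicate only needs a
#: representative Q, not the best achievable one.
_REPLICATE_RESTARTS = 5
#: Declared convention: observed max degree > mean + 3 sd ⇒ heavy-tailed.
HEAVY_TAIL_SD = 3.0


@dataclass(frozen=True)
class BaselineComparison:
    """Observed metrics vs a matched uniform random ensemble."""

    observed: dict[str, float]
    ensemble_mean: dict[str, float]
    ensemble_sd: dict[str, float]
    z_scores: dict[str, float | None]        # None where sd == 0 (degenerate)
    heavy_tail: dict[str, bool]              # keys "in", "out"
    n_replicates: int
    n_replicates_used: int
    seed: int

    @property
    def heavy_tail_flag(self) -> bool:
        """True when either degree direction clears the 3-sigma rule."""
        return self.heavy_tail["in"] or self.heavy_tail["out"]

    def to_json(self) -> str:
        return json.dumps({
            "observed": self.observed,
            "ensemble_mean": self.ensemble_mean,
            "ensemble_sd": self.ensemble_sd,
            "z_scores": self.z_scores,
            "heavy_tail": self.heavy_tail,
            "heavy_tail_flag": self.heavy_tail_flag,
            "n_replicates": self.n_replicates,
            "n_replicates_used": self.n_replicates_used,
            "seed": self.seed,
        }, indent=2, sort_keys=True) + "\n"

    def format_table(self) -> str:
        lines = [f"{'metric':<16}{'observed':>10}{'mean':>10}{'sd':>10}{'z':>8}"]
        for k in _METRICS:
            z = self.z_scores[k]
            zs = "  undef" if z is None else f"{z:8.2f}"
            lines.append(f"{k:<16}{self.observed[k]:>10.3f}"
                         f"{self.ensemble_mean[k]:>10.3f}{self.ensemble_sd[k]:>10.3f}{zs}")
        lines.append(f"heavy-tailed in-degree:  {self.heavy_tail['in']}")
        lines.append(f"heavy-tailed out-degree: {self.heavy_tail['out']}")
        return "\n".join(lines) + "\n"


def _metrics_of(g: CLDGraph, seed: int, restarts: int) -> dict[str, float]:
    apl, _ = average_path_length(g)
    diam, _ = diameter(g)
    q = louvain(g, seed=seed, restarts=restarts).modularity
    return {
        "avg_path_length": apl,
        "diameter": float(diam),
        "modularity": q,
        "max_in_degree": float(degree_distribution(g, "in").max),
        "max_out_degree": float(degree_distribution(g, "out").max),
    }


def compare_to_random(g: CLDGraph, n_replicates: int = 20,
                      seed: int = 0) -> BaselineComparison:
    """Compare a CLD's topology against matched uniform random graphs.

    Generates ``n_replicates`` directed G(N, E) graphs (seeded, so the
    whole comparison is reproducible bit-for-bit), computes average path
    length, diameter, modularity and degree maxima for each, and
    reports per-metric z-scores plus the 3-sigma heavy-tail flags.
    Replicates with no reachable pair are skipped with a warning.
    """
    if n_replicates < 10:
        raise ValueError("need at least 10 replicates for a meaningful baseline")
    observed = _metrics_of(g, seed=seed, restarts=_REPLICATE_RESTARTS)
    rows: list[dict[str, float]] = []
    for r in range(n_replicates):
        rep = er_directed(g.n_nodes, g.n_edges, seed=int(np.random.default_rng(
            [seed, 0xBA5E, r]).integers(2**31)))
        try:
            rows.append(_metrics_of(rep, seed=seed, restarts=_REPLICATE_RESTARTS))
        except UndefinedMetricError:
            logger.warning("baseline replicate %d has no reachable pair; skipped", r)
    if not rows:
        raise UndefinedMetricError("every baseline replicate was degenerate")
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    z: dict[str, float | None] = {}
    for k in _METRICS:
        vals = np.array([row[k] for row in rows], dtype=float)
        mean[k] = float(vals.mean())
        sd[k] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        z[k] = (observed[k] - mean[k]) / sd[k] if sd[k] > 0 else None
    heavy = {
        "in": observed["max_in_degree"] > mean["max_in_degree"] + HEAVY_TAIL_SD * sd["max_in_degree"],
        "out": observed["max_out_degree"] > mean["max_out_degree"] + HEAVY_TAIL_SD * sd["max_out_degree"],
    }
    return BaselineComparison(observed=observed, ensemble_mean=mean, ensemble_sd=sd,
                              z_scores=z, heavy_tail=heavy,
                              n_replicates=n_replicates, n_replicates_used=len(rows),
                              seed=seed)
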