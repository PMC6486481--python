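"""Reaction flux maps and condition-vs-control flux comparisons.

A flux map is a directed multigraph over composition keys: one edge per
(substrate, product, enzyme) triple, weighted by the number of reaction
events observed in a simulation, with the final-profile abundance attached
to each node.  On top of it: ranking an enzyme's reactions by flux,
normalized condition/control flux ratios (used to ask which substrates an
enzyme prefers after a perturbation, normalized by its total flux), and the
GalT titration that probes how galactosylation activity controls antenna
branching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import pandas as pd

from .notation import antenna_count, classify, GlycanClass
from .simulator import GolgiModel, GlycanProfile, simulate_profile

__all__ = [
    "FluxMap",
    "FluxRatioReport",
    "build_flux_map",
    "top_reactions",
    "normalized_flux_ratio",
    "galt_titration",
]

log = logging.getLogger(__name__)

Edge = tuple[str, str, str]  # substrate key, product key, enzyme


@dataclass
class FluxMap:
    """Composition-keyed reaction flux graph with the event log attached."""

    graph: nx.MultiDiGraph
    events: Optional[pd.DataFrame] = None

    def edge_counts(self) -> dict[Edge, int]:
        return {
            (u, v, enzyme): data["count"]
            for u, v, enzyme, data in self.graph.edges(keys=True, data=True)
        }

    def enzyme_total(self, enzyme: str) -> int:
        return sum(
            d["count"]
            for _, _, k, d in self.graph.edges(keys=True, data=True)
            if k == enzyme
        )

    def node_abundance(self, key: str) -> float:
        return self.graph.nodes[key].get("abundance", 0.0) if key in self.graph else 0.0


@dataclass
class FluxRatioReport:
    rows: pd.DataFrame  # columns: substrate, product, enzyme, ratio
    normalizer: tuple[float, float]  # condition total, control total
    omitted: list[Edge] = field(default_factory=list)


def build_flux_map(events: pd.DataFrame, profile: GlycanProfile) -> FluxMap:
    """Aggregate an event log into a flux map.

    Edges are keyed at composition level (isoforms collated, like profiles);
    quench events appear as self-loops.  Node ``abundance`` is the final
    profile abundance (0 for compositions filtered out or fully consumed).
    """
    g = nx.MultiDiGraph()
    if events is not None and len(events):
        grouped = events.groupby(
            ["substrate_key", "product_key", "enzyme"], sort=True
        ).size()
        for (sub, prod, enzyme), count in grouped.items():
            g.add_edge(sub, prod, key=enzyme, count=int(count))
    for node in g.nodes:
        g.nodes[node]["abundance"] = profile.entries.get(node, 0.0)
    for key, ab in profile.entries.items():
        if key not in g:
            g.add_node(key, abundance=ab)
    return FluxMap(g, events)


def top_reactions(flux_map: FluxMap, enzyme: str, k: int = 6) -> list[tuple[Edge, int]]:
    """The enzyme's k highest-flux edges, ties broken by substrate then
    product key; empty when the enzyme produced no events."""
    if k < 1:
        raise ValueError("k must be >= 1")
    edges = [
        (edge, count) for edge, count in flux_map.edge_counts().items() if edge[2] == enzyme
    ]
    edges.sort(key=lambda ec: (-ec[1], ec[0][0], ec[0][1]))
    return edges[:k]


def normalized_flux_ratio(
    condition: FluxMap,
    control: FluxMap,
    normalizing_enzyme: str = "FUT8",
    variant: str = "divide",
) -> FluxRatioReport:
    """Per-edge condition/control flux ratios normalized by the ratio of the
    total flux of ``normalizing_enzyme``.

    The default "divide" form is (f_cond/f_ctrl) / (F_cond/F_ctrl): values
    above 1 indicate a pathway preferred in the condition.  ``variant=
    "multiply"`` exposes the alternative (f_cond/f_ctrl) * (F_cond/F_ctrl)
    normalization.  Edges with zero control flux are omitted and logged.
    """
    if variant not in ("divide", "multiply"):
        raise ValueError("variant must be 'divide' or 'multiply'")
    f_cond_total = condition.enzyme_total(normalizing_enzyme)
    f_ctrl_total = control.enzyme_total(normalizing_enzyme)
    if f_cond_total == 0 or f_ctrl_total == 0:
        raise ValueError(
            f"total {normalizing_enzyme} flux is zero in "
            f"{'condition' if f_cond_total == 0 else 'control'} map"
        )
    norm = f_cond_total / f_ctrl_total
    cond_edges = condition.edge_counts()
    ctrl_edges = control.edge_counts()
    rows = []
    omitted = []
    for edge in sorted(set(cond_edges) | set(ctrl_edges)):
        fc = cond_edges.get(edge, 0)
        f0 = ctrl_edges.get(edge, 0)
        if f0 == 0:
            omitted.append(edge)
            log.info("edge %s has zero control flux; omitted", edge)
            continue
        raw = fc / f0
        ratio = raw / norm if variant == "divide" else raw * norm
        rows.append(
            {"substrate": edge[0], "product": edge[1], "enzyme": edge[2], "ratio": ratio}
        )
    return FluxRatioReport(
        rows=pd.DataFrame(rows, columns=["substrate", "product", "enzyme", "ratio"]),
        normalizer=(f_cond_total, f_ctrl_total),
        omitted=omitted,
    )


def galt_titration(
    model: GolgiModel,
    galt_multipliers: list[float],
    n_glycans: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Scale all GalT cisternal rates by each multiplier, simulate, and
    report the summed abundance of tri- and tetra-antennary complex glycans.

    Returns a DataFrame (multiplier, pct_triantennary, pct_tetraantennary).
    Antenna counts are tallied on the final structures, not inferred from
    composition keys.
    """
    rows = []
    for j, mult in enumerate(galt_multipliers):
        if mult < 0:
            raise ValueError("GalT multipliers must be >= 0")
        scaled = model.scaled({"GalT": mult})
        tri, tetra = _antennary_shares(scaled, n_glycans, seed)
        rows.append(
            {"multiplier": mult, "pct_triantennary": tri, "pct_tetraantennary": tetra}
        )
    return pd.DataFrame(rows)


def _antennary_shares(model: GolgiModel, n_glycans: int, seed: int) -> tuple[float, float]:
    import numpy as np

    from .simulator import _simulate_final_states

    compiled, final, _ = _simulate_final_states(model, n_glycans, seed)
    counts = np.bincount(final, minlength=compiled.n_states)
    tri = tetra = 0
    for idx, c in enumerate(counts):
        if c == 0:
            continue
        g = compiled.state_structures[idx]
        if classify(g) is not GlycanClass.COMPLEX:
            continue
        ants = antenna_count(g)
        if ants == 3:
            tri += c
        elif ants == 4:
            tetra += c
    return 100.0 * tri / n_glycans, 100.0 * tetra / n_glycans
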