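"""Structural analyses of imported networks.

Out-degree distributions, weakly connected components and sink nodes --
the descriptive statistics typically inspected after merging pathways and
before simulating.  Automatic self-degradation loops are excluded
throughout so the numbers reflect the curated interaction structure, not
the simulation plumbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Set

import networkx as nx

from .model import SELF_DEGRADATION, Network


@dataclass
class DegreeHistogram:
    """Out-degree -> node count, plus the most out-connected nodes."""

    counts: Dict[int, int] = field(default_factory=dict)
    argmax_nodes: List[str] = field(default_factory=list)

    def to_rows(self) -> list:
        return [
            {"out_degree": d, "nodes": self.counts[d]} for d in sorted(self.counts)
        ]


def _structural_graph(network: Network) -> nx.MultiDiGraph:
    """networkx view of the network without self-degradation loops."""
    g = nx.MultiDiGraph()
    g.add_nodes_from(network.nodes)
    for e in network.edges.values():
        if e.interaction_type == SELF_DEGRADATION and e.source == e.target:
            continue
        g.add_edge(e.source, e.target, key=e.interaction_type, weight=e.weight)
    return g


def out_degree_distribution(network: Network) -> DegreeHistogram:
    """Out-degree histogram, self-degradation loops excluded; ties in the
    argmax are listed alphabetically."""
    g = _structural_graph(network)
    degrees = dict(g.out_degree())
    hist = DegreeHistogram()
    for d in degrees.values():
        hist.counts[d] = hist.counts.get(d, 0) + 1
    if degrees:
        top = max(degrees.values())
        hist.argmax_nodes = sorted(n for n, d in degrees.items() if d == top)
    return hist


def connected_components(network: Network, min_size: int = 1) -> List[Set[str]]:
    """Weakly connected components, largest first; components smaller than
    ``min_size`` are dropped (e.g. ``min_size=9`` excludes subnetworks of
    8 nodes or less)."""
    g = _structural_graph(network)
    comps = [set(c) for c in nx.weakly_connected_components(g)]
    comps = [c for c in comps if len(c) >= min_size]
    return sorted(comps, key=lambda c: (-len(c), sorted(c)))


def sink_nodes(network: Network) -> Set[str]:
    """Nodes with no outgoing edges other than their self-degradation loop."""
    g = _structural_graph(network)
    return {n for n, d in g.out_degree() if d == 0}
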