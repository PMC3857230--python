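"""Construction of unweighted chromatin interaction networks.

Fragments are nodes and interaction calls passing an FDR threshold are
edges of weight 1. Networks are built from one interaction class —
inter-chromosomal, intra-chromosomal, or their union ("complete") — and
then restricted to the largest connected component, so isolated nodes
never appear. Lowering the threshold can only remove edges; the stringent
network is always a subnetwork of the lenient one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from .io import FragmentSet, InteractionRecord

__all__ = [
    "InteractionNetwork",
    "EmptyNetworkError",
    "build_network",
    "subnetwork",
    "network_stats",
]

CLASSES = ("inter", "intra", "complete")


class EmptyNetworkError(ValueError):
    """No edges survive class/threshold filtering."""


@dataclass
class InteractionNetwork:
    """An unweighted, connected graph over fragment ids.

    ``graph`` is a simple undirected networkx Graph (every edge weight 1,
    no self-loops, no parallel edges) restricted to the largest connected
    component of the filtered interaction data.
    """

    graph: nx.Graph
    cls: str = "complete"
    fdr_threshold: float = 1.0

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def m(self) -> int:
        """Total edge weight = edge count (all weights are 1)."""
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree[node]


def _lcc(graph: nx.Graph) -> nx.Graph:
    if graph.number_of_nodes() == 0:
        return graph
    # deterministic choice among equal-sized components: lexicographically
    # smallest member breaks ties
    components = sorted(
        nx.connected_components(graph), key=lambda c: (-len(c), min(c))
    )
    return graph.subgraph(components[0]).copy()


def build_network(
    records: Iterable[InteractionRecord],
    fragments: FragmentSet,
    cls: str = "complete",
    fdr_threshold: float = 0.01,
) -> InteractionNetwork:
    """Build the interaction network for one class at one FDR threshold.

    An edge is included iff the record's FDR is <= ``fdr_threshold``
    (ties pass) and its class matches the selector ("complete" keeps
    both). The result is the largest connected component of the filtered
    graph.

    Raises
    ------
    EmptyNetworkError
        If no edge survives filtering.
    """
    if cls not in CLASSES:
        raise ValueError(f"cls must be one of {CLASSES}, got {cls!r}")
    if not (0.0 < fdr_threshold <= 1.0):
        raise ValueError(f"fdr_threshold must be in (0, 1], got {fdr_threshold}")
    graph = nx.Graph()
    for rec in records:
        if rec.fdr > fdr_threshold:
            continue
        if cls != "complete" and rec.cls != cls:
            continue
        for frag_id in rec.pair:
            if frag_id not in fragments:
                raise KeyError(f"interaction references unknown fragment {frag_id!r}")
        graph.add_edge(rec.frag_a, rec.frag_b)
    if graph.number_of_edges() == 0:
        raise EmptyNetworkError(
            f"no {cls} interactions at FDR <= {fdr_threshold}"
        )
    return InteractionNetwork(_lcc(graph), cls=cls, fdr_threshold=fdr_threshold)


def subnetwork(network: InteractionNetwork, node_subset: Iterable[str]) -> InteractionNetwork:
    """Induced subgraph on ``node_subset``, restricted to its largest component.

    Used to treat one community as an independent network for a second
    round of partitioning.
    """
    subset = set(node_subset)
    unknown = subset - network.nodes
    if unknown:
        raise KeyError(f"nodes not in network: {sorted(unknown)[:5]}")
    induced = network.graph.subgraph(subset).copy()
    return InteractionNetwork(
        _lcc(induced), cls=network.cls, fdr_threshold=network.fdr_threshold
    )


def network_stats(network: InteractionNetwork) -> dict:
    """Node count, edge count and degree distribution summary."""
    degrees = [d for _, d in network.graph.degree]
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    assert sum(degrees) == 2 * network.m
    return {
        "n_nodes": network.n_nodes,
        "n_edges": network.m,
        "degree_min": min(degrees) if degrees else 0,
        "degree_max": max(degrees) if degrees else 0,
        "degree_mean": (sum(degrees) / len(degrees)) if degrees else 0.0,
        "degree_hist": dict(sorted(hist.items())),
    }
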