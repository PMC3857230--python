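"""Modularity and hierarchical Louvain community detection.

A community partition assigns every node a community id; its quality is
the modularity

    Q = (1/2m) * sum_ij [A_ij - k_i*k_j/(2m)] * delta(c_i, c_j)

where A is the adjacency matrix, m the total edge weight, k_i the
(weighted) degree of node i and delta the Kronecker delta over community
membership. Louvain greedily maximises Q in two alternating phases:
local moves (each node relocates to the neighbouring community with the
largest positive gain until a full sweep produces no move) and
aggregation (each community collapses to one node; intra-community
weight becomes a self-loop). Each aggregation round is recorded as one
hierarchical level: level 0 is the finest partition, the top level is
the final solution, and recorded modularity never decreases with level.

The algorithm is a heuristic — modularity maximisation is NP-complete —
but on small benchmark graphs it recovers the exhaustive-search optimum
(see the test suite), and its hierarchical levels expose intermediate
community structure.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Mapping

import networkx as nx

from .network import InteractionNetwork, subnetwork

__all__ = [
    "modularity",
    "louvain",
    "filter_small",
    "repartition_communities",
    "HierarchicalPartition",
    "FilteredPartition",
    "community_sizes",
]


def _as_graph(network) -> nx.Graph:
    return network.graph if isinstance(network, InteractionNetwork) else network


def modularity(network, assignment: Mapping) -> float:
    """Newman modularity of a partition of a simple graph.

    ``assignment`` must cover every node. Edge weights are honoured
    (attribute ``weight``, default 1); the public interaction networks
    are unweighted so every edge counts 1.
    """
    graph = _as_graph(network)
    for node in graph.nodes:
        if node not in assignment:
            raise KeyError(f"node {node!r} missing from assignment")
    if any(u == v for u, v in graph.edges):
        raise ValueError("modularity is defined here for graphs without self-loops")
    m = graph.size(weight="weight")
    if m == 0:
        return 0.0
    deg = dict(graph.degree(weight="weight"))
    internal: dict = {}
    for u, v, w in graph.edges(data="weight", default=1):
        if assignment[u] == assignment[v]:
            internal[assignment[u]] = internal.get(assignment[u], 0.0) + w
    deg_sum: dict = {}
    for node, k in deg.items():
        c = assignment[node]
        deg_sum[c] = deg_sum.get(c, 0.0) + k
    q = 0.0
    for c, k_c in deg_sum.items():
        q += internal.get(c, 0.0) / m - (k_c / (2.0 * m)) ** 2
    return q


@dataclass
class HierarchicalPartition:
    """Louvain solution: one node->community map per hierarchical level.

    ``levels[0]`` is the finest partition; ``levels[-1]`` (the top level)
    is the final solution. Every level is a coarsening of the level
    below, and ``modularities`` is non-decreasing.
    """

    levels: list[dict]
    modularities: list[float]

    @property
    def final(self) -> dict:
        return self.levels[-1]

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def sizes(self, level: int = -1) -> dict[int, int]:
        return community_sizes(self.levels[level])


def community_sizes(assignment: Mapping) -> dict[int, int]:
    sizes: dict[int, int] = {}
    for c in assignment.values():
        sizes[c] = sizes.get(c, 0) + 1
    return dict(sorted(sizes.items()))


# -- internal weighted-graph representation for the Louvain phases --------
# adjacency: dict u -> dict v -> weight, symmetric; self-loop stored once
# at adj[u][u]; weighted degree counts a self-loop twice.


def _weighted_adj(graph: nx.Graph) -> dict:
    adj: dict = {u: {} for u in graph.nodes}
    for u, v, w in graph.edges(data="weight", default=1):
        if u == v:
            adj[u][u] = adj[u].get(u, 0.0) + w
        else:
            adj[u][v] = adj[u].get(v, 0.0) + w
            adj[v][u] = adj[v].get(u, 0.0) + w
    return adj


def _degrees(adj: dict) -> dict:
    return {
        u: sum(nbrs.values()) + nbrs.get(u, 0.0) for u, nbrs in adj.items()
    }


def _one_level(
    adj: dict, order: list, min_gain: float
) -> tuple[dict, bool]:
    """Local-moving phase. Returns (node->community, any_move_made).

    Each node is relocated to the neighbouring community with maximal
    positive modularity gain; ties break to the lowest community id;
    sweeps repeat in a fixed node order until one full sweep yields no
    move.
    """
    k = _degrees(adj)
    m2 = sum(k.values())  # 2m
    node2com = {u: i for i, u in enumerate(order)}
    com_tot = {node2com[u]: k[u] for u in order}
    if m2 == 0:
        return node2com, False
    moved_ever = False
    while True:
        moved = False
        for u in order:
            old = node2com[u]
            # weights from u to each neighbouring community (self-loop excluded)
            links: dict[int, float] = {}
            for v, w in adj[u].items():
                if v == u:
                    continue
                c = node2com[v]
                links[c] = links.get(c, 0.0) + w
            com_tot[old] -= k[u]
            # gain of joining c, up to a common 1/m factor:
            #   k_{u,c} - k_u * tot_c / (2m)
            def gain(c: int) -> float:
                return links.get(c, 0.0) - k[u] * com_tot.get(c, 0.0) / m2

            best, best_gain = old, gain(old)
            for c in sorted(links):
                g = gain(c)
                if g > best_gain + 1e-15 or (
                    abs(g - best_gain) <= 1e-15 and c < best
                ):
                    best, best_gain = c, g
            if best != old and best_gain - gain(old) > min_gain:
                node2com[u] = best
                com_tot[best] = com_tot.get(best, 0.0) + k[u]
                moved = True
                moved_ever = True
            else:
                com_tot[old] += k[u]
                node2com[u] = old
        if not moved:
            break
    return node2com, moved_ever


def _renumber(node2com: dict, order: list) -> dict:
    """Community ids 0..k-1 in order of first appearance along ``order``."""
    mapping: dict = {}
    for u in order:
        c = node2com[u]
        if c not in mapping:
            mapping[c] = len(mapping)
    return {u: mapping[node2com[u]] for u in node2com}


def _aggregate(adj: dict, node2com: dict) -> dict:
    between: dict = {}
    selfw: dict = {}
    for u, nbrs in adj.items():
        cu = node2com[u]
        for v, w in nbrs.items():
            if v == u:
                selfw[cu] = selfw.get(cu, 0.0) + w
                continue
            cv = node2com[v]
            if cu == cv:
                # each intra edge visited twice in this directed sweep
                selfw[cu] = selfw.get(cu, 0.0) + w / 2.0
            else:
                between.setdefault(cu, {})[cv] = between.get(cu, {}).get(cv, 0.0) + w
    coms = sorted(set(node2com.values()))
    new: dict = {c: {} for c in coms}
    for cu, nbrs in between.items():
        for cv, w in nbrs.items():
            new[cu][cv] = w
    for c, w in selfw.items():
        if w:
            new[c][c] = w
    return new


def louvain(network, seed: int = 1, min_gain: float = 0.0) -> HierarchicalPartition:
    """Hierarchical Louvain partition of a network.

    Parameters
    ----------
    network : InteractionNetwork or networkx.Graph
        Disconnected graphs are handled natively (each component is
        partitioned independently), which the random-graph null model
        relies on.
    seed : int
        Seeds the node-sweep shuffle (one shuffle per level), making the
        solution reproducible.
    min_gain : float
        Minimum modularity improvement required to accept a move;
        0 demands strict improvement.
    """
    if min_gain < 0:
        raise ValueError("min_gain must be >= 0")
    graph = _as_graph(network)
    orig_nodes = list(graph.nodes)
    if not orig_nodes:
        raise ValueError("cannot partition an empty graph")
    rng = random.Random(seed)
    adj = _weighted_adj(graph)
    node2coarse = {u: u for u in orig_nodes}
    levels: list[dict] = []
    mods: list[float] = []
    while True:
        order = list(adj)
        rng.shuffle(order)
        part, moved = _one_level(adj, order, min_gain)
        if levels and not moved:
            break
        part = _renumber(part, list(adj))
        level_assign = {u: part[node2coarse[u]] for u in orig_nodes}
        levels.append(level_assign)
        mods.append(modularity(graph, level_assign))
        if not moved:
            break
        node2coarse = {u: part[node2coarse[u]] for u in orig_nodes}
        adj = _aggregate(adj, part)
        if len(adj) == len(set(part.values())) == 1:
            break
    return HierarchicalPartition(levels=levels, modularities=mods)


@dataclass
class FilteredPartition:
    """A partition level with small communities set aside.

    ``communities`` maps retained community ids (>= ``min_size`` members)
    to their node sets; ``unassigned`` holds every node whose community
    fell below the size cutoff. Retained and unassigned nodes together
    cover the network.
    """

    communities: dict[int, set]
    unassigned: set
    min_size: int = 10


def filter_small(assignment: Mapping, min_size: int = 10) -> FilteredPartition:
    """Drop communities with fewer than ``min_size`` nodes (default 10).

    Small chains of nodes at the network edges are not robust
    communities; the members of dropped communities are reported as
    unassigned rather than silently discarded.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    members: dict[int, set] = {}
    for node, c in assignment.items():
        members.setdefault(c, set()).add(node)
    retained = {c: nodes for c, nodes in members.items() if len(nodes) >= min_size}
    unassigned = set().union(
        *(nodes for c, nodes in members.items() if c not in retained), set()
    )
    return FilteredPartition(
        communities=dict(sorted(retained.items())),
        unassigned=unassigned,
        min_size=min_size,
    )


def repartition_communities(
    network: InteractionNetwork,
    filtered: FilteredPartition,
    seed: int = 1,
) -> dict[int, HierarchicalPartition]:
    """Second-round Louvain on the subnetwork of each retained community.

    Each community's induced subnetwork (restricted to its largest
    connected component) is treated as an independent network. Results
    are keyed by the parent community id; the per-community seed is
    ``seed + parent_id`` so runs are reproducible community by community.
    """
    out: dict[int, HierarchicalPartition] = {}
    for parent_id, nodes in sorted(filtered.communities.items()):
        sub = subnetwork(network, nodes)
        out[parent_id] = louvain(sub, seed=seed + parent_id)
    return out
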