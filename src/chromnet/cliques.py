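"""Maximal clique enumeration and clique-size/signal trends.

Large cliques are unlikely to arise by chance in a sparse network, so
genomic regions belonging to large cliques represent sets of loci with
relatively robust, stable interactions. Each node is assigned its maximum
clique size — the size of the largest maximal clique containing it — and
continuous signals (cohesin enrichment, replication timing, ...) are
summarised per size class. The trend statistic is Spearman's rank
correlation between the per-class mean signal and the clique size, one
observation per distinct size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .network import InteractionNetwork

__all__ = [
    "enumerate_maximal_cliques",
    "max_clique_size_per_node",
    "signal_by_clique_size",
    "CliqueProfile",
    "CliqueSignalTrend",
]


def _as_adjacency(network) -> dict:
    graph = network.graph if isinstance(network, InteractionNetwork) else network
    return {u: set(graph.neighbors(u)) - {u} for u in graph.nodes}


def enumerate_maximal_cliques(network) -> list[frozenset]:
    """Enumerate all maximal cliques (Bron–Kerbosch with pivoting).

    The recursion explores candidates in sorted-id order and picks as
    pivot the candidate with the most neighbours still in play (ties to
    the smallest id), so the enumeration order is reproducible. Accepts
    an :class:`InteractionNetwork` or a networkx graph.
    """
    adj = _as_adjacency(network)
    cliques: list[frozenset] = []
    if not adj:
        return cliques

    def expand(r: set, p: set, x: set) -> None:
        if not p and not x:
            cliques.append(frozenset(r))
            return
        # pivot u maximizing |P ∩ N(u)| prunes the most branches
        pivot = max(sorted(p | x), key=lambda u: len(p & adj[u]))
        for v in sorted(p - adj[pivot]):
            expand(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    expand(set(), set(adj), set())
    return cliques


@dataclass
class CliqueProfile:
    """Per-node maximum clique size and the node groups per size."""

    sizes: dict[str, int]

    @property
    def groups(self) -> dict[int, list]:
        out: dict[int, list] = {}
        for node in sorted(self.sizes, key=str):
            out.setdefault(self.sizes[node], []).append(node)
        return dict(sorted(out.items()))

    @property
    def max_size(self) -> int:
        return max(self.sizes.values())


def max_clique_size_per_node(cliques: list[frozenset]) -> CliqueProfile:
    """Assign every node the cardinality of the largest clique containing it."""
    sizes: dict[str, int] = {}
    for clique in cliques:
        k = len(clique)
        for node in clique:
            if sizes.get(node, 0) < k:
                sizes[node] = k
    assert sizes, "no cliques supplied"
    return CliqueProfile(sizes)


@dataclass
class CliqueSignalTrend:
    """Signal summaries per clique-size class and the overall trend.

    ``per_size`` maps clique size -> (n nodes with signal, mean, IQR).
    ``scc`` is Spearman's rank correlation over the (size, mean) pairs,
    or None when fewer than 3 size classes carry signal or all class
    means are tied.
    """

    per_size: dict[int, tuple[int, float, float]]
    scc: float | None

    @property
    def sizes(self) -> list[int]:
        return sorted(self.per_size)


def signal_by_clique_size(
    profile: CliqueProfile, signal: Mapping[str, float]
) -> CliqueSignalTrend:
    """Summarise a per-fragment signal by maximum clique size.

    Nodes with a missing (absent or NaN) signal value are dropped from
    their class; size classes with no remaining node are dropped
    entirely. Means are unweighted over nodes; dispersion is the IQR.
    """
    per_size: dict[int, tuple[int, float, float]] = {}
    for size, nodes in profile.groups.items():
        values = [
            signal[n]
            for n in nodes
            if n in signal and signal[n] is not None and not math.isnan(signal[n])
        ]
        if not values:
            continue
        arr = np.asarray(values, dtype=float)
        iqr = float(np.percentile(arr, 75) - np.percentile(arr, 25))
        per_size[size] = (len(values), float(arr.mean()), iqr)
    scc: float | None = None
    if len(per_size) >= 3:
        sizes = sorted(per_size)
        means = [per_size[s][1] for s in sizes]
        if len(set(means)) > 1:
            rho = stats.spearmanr(sizes, means).statistic
            scc = None if math.isnan(rho) else float(rho)
    return CliqueSignalTrend(per_size=per_size, scc=scc)
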