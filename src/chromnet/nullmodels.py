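"""Random-graph calibration of modularity and partition robustness.

A modularity value on its own has no meaning: partitions of random
graphs can score high. Each observed partition is therefore compared to
a G(n, m) ensemble — uniform simple graphs with the same node count
(order) and edge count (size) — each replicate partitioned with the same
algorithm, and summarised as a standard score

    z = (Q_obs - mean(Q_null)) / sd(Q_null)

plus the empirical exceedance probability.

Robustness to the edge-significance threshold is quantified by the
recapitulation rate: for each community C of the stringent-threshold
network, the largest fraction of C found inside a single community of
the lenient-threshold network, averaged (unweighted) over stringent
communities.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Callable, Mapping

import networkx as nx

from .community import HierarchicalPartition, louvain
from .network import InteractionNetwork

__all__ = [
    "random_gnm",
    "modularity_zscore",
    "recapitulation",
    "NullModularityResult",
    "RecapitulationResult",
]

logger = logging.getLogger(__name__)


def random_gnm(n: int, m: int, seed: int) -> nx.Graph:
    """Uniform random simple graph with exactly n nodes and m edges.

    Connectivity is deliberately not enforced: the null ensemble matches
    the observed network only in order and size, and Louvain partitions
    disconnected graphs natively.
    """
    max_edges = n * (n - 1) // 2
    if m > max_edges:
        raise ValueError(f"m={m} exceeds max simple-graph edges {max_edges} for n={n}")
    return nx.gnm_random_graph(n, m, seed=seed)


@dataclass
class NullModularityResult:
    """Observed modularity against a G(n, m) null ensemble."""

    observed_q: float
    null_qs: list[float]
    z: float | None
    empirical_p: float

    @property
    def null_mean(self) -> float:
        return statistics.fmean(self.null_qs)

    @property
    def null_sd(self) -> float:
        return statistics.stdev(self.null_qs)


def modularity_zscore(
    network,
    n_replicates: int = 10000,
    seed: int = 1,
    partition_fn: Callable[..., HierarchicalPartition] | None = None,
) -> NullModularityResult:
    """Standard score of a network's Louvain modularity over G(n, m) nulls.

    Each replicate draws an independent G(n, m) graph (replicate r uses
    seed ``seed + 1 + r``, so ensembles are reproducible and
    embarrassingly parallel), partitions it with the same algorithm, and
    records its top-level modularity. ``z`` is None when the null
    distribution is degenerate (sd = 0). ``empirical_p`` is the fraction
    of null modularities >= the observed one, the exceedance over the
    ensemble.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    if partition_fn is None:
        partition_fn = louvain
    graph = network.graph if isinstance(network, InteractionNetwork) else network
    n, m = graph.number_of_nodes(), graph.number_of_edges()
    observed = partition_fn(network, seed=seed).modularities[-1]
    null_qs: list[float] = []
    for r in range(n_replicates):
        rep_seed = seed + 1 + r
        g = random_gnm(n, m, seed=rep_seed)
        null_qs.append(partition_fn(g, seed=rep_seed).modularities[-1])
    mean = statistics.fmean(null_qs)
    sd = statistics.stdev(null_qs)
    z = (observed - mean) / sd if sd > 0 else None
    if z is None:
        logger.warning("degenerate null distribution (sd = 0); z undefined")
    empirical_p = sum(q >= observed for q in null_qs) / n_replicates
    return NullModularityResult(
        observed_q=observed, null_qs=null_qs, z=z, empirical_p=empirical_p
    )


@dataclass
class RecapitulationResult:
    """Cross-threshold community agreement.

    ``per_community`` maps each stringent community id to r_C, the
    largest fraction of its members lying in one lenient community;
    ``mean_recap`` is the unweighted mean of r_C; ``n_dropped`` counts
    stringent nodes absent from the lenient partition (excluded from the
    denominators).
    """

    per_community: dict[int, float]
    mean_recap: float
    n_dropped: int


def recapitulation(
    partition_stringent: Mapping,
    partition_lenient: Mapping,
) -> RecapitulationResult:
    """Fraction of each stringent community contained in one lenient community.

    Both arguments are node->community maps (apply the community size
    filter first if desired). The result is invariant to community
    relabeling on either side, and ``mean_recap`` is 1 exactly when every
    stringent community is wholly contained in a single lenient
    community.
    """
    dropped = [u for u in partition_stringent if u not in partition_lenient]
    if dropped:
        logger.info(
            "%d stringent nodes absent from lenient partition; dropped", len(dropped)
        )
    members: dict[int, list] = {}
    for node, c in partition_stringent.items():
        if node in partition_lenient:
            members.setdefault(c, []).append(node)
    if not members:
        raise ValueError("no stringent community has nodes present in both partitions")
    per_community: dict[int, float] = {}
    for c, nodes in members.items():
        counts: dict = {}
        for node in nodes:
            d = partition_lenient[node]
            counts[d] = counts.get(d, 0) + 1
        per_community[c] = max(counts.values()) / len(nodes)
    mean_recap = statistics.fmean(per_community.values())
    return RecapitulationResult(
        per_community=dict(sorted(per_community.items())),
        mean_recap=mean_recap,
        n_dropped=len(dropped),
    )
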