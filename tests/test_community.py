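import random

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from chromnet.community import (
    filter_small,
    louvain,
    modularity,
    repartition_communities,
)
from chromnet.io import Fragment, FragmentSet
from chromnet.network import build_network

from conftest import make_records


def double_sum_modularity(graph: nx.Graph, assignment) -> float:
    """Independent O(n^2) oracle: literal double sum over the adjacency matrix."""
    nodes = list(graph.nodes)
    A = nx.to_numpy_array(graph, nodelist=nodes)
    m = graph.number_of_edges()
    k = A.sum(axis=1)
    q = 0.0
    for i in range(len(nodes)):
        for j in range(len(nodes)):
            if assignment[nodes[i]] == assignment[nodes[j]]:
                q += A[i, j] - k[i] * k[j] / (2 * m)
    return q / (2 * m)


def set_partitions(items):
    """All partitions of a set (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1:]
        yield [[first]] + partition


class TestModularity:
    def test_two_disjoint_edges_by_component(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        assert modularity(g, {"a": 0, "b": 0, "c": 1, "d": 1}) == pytest.approx(0.5, abs=1e-15)

    def test_triangle_singletons(self):
        g = nx.complete_graph(3)
        assert modularity(g, {0: 0, 1: 1, 2: 2}) == pytest.approx(-1 / 3, abs=1e-15)

    def test_single_community_is_zero(self):
        # with every node in one community the double sum telescopes:
        # sum_ij A_ij = 2m and sum_ij k_i k_j = (2m)^2, so Q = 0 identically
        g = nx.gnm_random_graph(12, 30, seed=1)
        assignment = {u: 0 for u in g.nodes}
        assert modularity(g, assignment) == pytest.approx(0.0, abs=1e-15)
        assert double_sum_modularity(g, assignment) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_double_sum_oracle(self, seed):
        rng = random.Random(seed)
        n = rng.randint(5, 25)
        g = nx.gnm_random_graph(n, rng.randint(n - 1, n * (n - 1) // 2), seed=seed)
        assignment = {u: rng.randint(0, 3) for u in g.nodes}
        assert modularity(g, assignment) == pytest.approx(
            double_sum_modularity(g, assignment), abs=1e-12
        )

    def test_missing_node_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(KeyError):
            modularity(g, {0: 0, 1: 0})


class TestLouvain:
    def test_bridged_triangles_reach_exhaustive_optimum(self, bridged_triangles):
        """The 6-node two-triangle graph has a known optimum (the two
        triangles, Q = 5/14) verified by enumerating all 203 partitions."""
        best_q = max(
            modularity(bridged_triangles, {u: i for i, block in enumerate(p) for u in block})
            for p in set_partitions(bridged_triangles.nodes)
        )
        assert best_q == pytest.approx(5 / 14, abs=1e-12)
        part = louvain(bridged_triangles, seed=1)
        assert part.modularities[-1] == pytest.approx(5 / 14, abs=1e-12)
        final = part.final
        assert {frozenset(u for u in final if final[u] == c) for c in set(final.values())} == {
            frozenset({0, 1, 2}), frozenset({3, 4, 5})
        }

    def test_complete_graph_stays_whole(self):
        part = louvain(nx.complete_graph(5), seed=3)
        assert len(set(part.final.values())) == 1

    def test_ring_of_cliques_recovers_planted_blocks(self):
        g = nx.ring_of_cliques(4, 8)
        part = louvain(g, seed=2)
        planted = [u // 8 for u in g.nodes]
        predicted = [part.final[u] for u in g.nodes]
        assert adjusted_rand_score(planted, predicted) == 1.0

    def test_reported_modularity_matches_recomputation(self):
        g = nx.gnm_random_graph(60, 180, seed=5)
        part = louvain(g, seed=5)
        for level, q in zip(part.levels, part.modularities):
            assert modularity(g, level) == pytest.approx(q, abs=1e-12)

    def test_levels_are_coarsenings_with_nondecreasing_modularity(self):
        g = nx.ring_of_cliques(6, 5)
        part = louvain(g, seed=7)
        for lower, upper in zip(part.levels, part.levels[1:]):
            image = {}
            for node in lower:
                c = lower[node]
                if c in image:
                    assert image[c] == upper[node]
                else:
                    image[c] = upper[node]
        assert all(b >= a - 1e-12 for a, b in zip(part.modularities, part.modularities[1:]))

    def test_community_ids_sequential_from_zero(self):
        g = nx.ring_of_cliques(4, 6)
        part = louvain(g, seed=1)
        for level in part.levels:
            ids = set(level.values())
            assert ids == set(range(len(ids)))

    def test_single_node_graph(self):
        g = nx.Graph()
        g.add_node("only")
        part = louvain(g, seed=1)
        assert part.final == {"only": 0}

    def test_reproducible_under_seed(self):
        g = nx.gnm_random_graph(80, 240, seed=9)
        assert louvain(g, seed=4).levels == louvain(g, seed=4).levels

    def test_planted_sbm_recovery(self):
        """4 planted blocks of 25 nodes (p_in=0.3, p_out=0.01) are recovered
        nearly perfectly, averaged over seeds."""
        probs = [[0.3 if i == j else 0.01 for j in range(4)] for i in range(4)]
        aris = []
        for seed in range(5):
            g = nx.stochastic_block_model([25] * 4, probs, seed=seed)
            part = louvain(g, seed=seed + 1)
            aris.append(
                adjusted_rand_score([u // 25 for u in g.nodes], [part.final[u] for u in g.nodes])
            )
        assert np.mean(aris) >= 0.95


class TestFilterAndRepartition:
    def _assignment(self, sizes):
        assignment = {}
        i = 0
        for c, size in enumerate(sizes):
            for _ in range(size):
                assignment[f"n{i}"] = c
                i += 1
        return assignment

    def test_small_communities_become_unassigned(self):
        filtered = filter_small(self._assignment([120, 40, 3]), min_size=10)
        assert sorted(len(v) for v in filtered.communities.values()) == [40, 120]
        assert len(filtered.unassigned) == 3

    def test_min_size_one_is_identity(self):
        assignment = self._assignment([4, 2])
        filtered = filter_small(assignment, min_size=1)
        assert filtered.unassigned == set()
        assert sum(len(v) for v in filtered.communities.values()) == len(assignment)

    def test_all_below_cutoff_allowed(self):
        filtered = filter_small(self._assignment([3, 2]), min_size=10)
        assert filtered.communities == {}
        assert len(filtered.unassigned) == 5

    def _two_bridged_cliques_network(self):
        frags = FragmentSet(
            Fragment(f"f{i}", "chrI", i * 100, (i + 1) * 100) for i in range(10)
        )
        pairs = [(f"f{i}", f"f{j}", 0.001) for i in range(5) for j in range(i + 1, 5)]
        pairs += [(f"f{i}", f"f{j}", 0.001) for i in range(5, 10) for j in range(i + 1, 10)]
        pairs += [("f4", "f5", 0.001)]
        return build_network(make_records(pairs, frags), frags, cls="complete")

    def test_repartition_splits_bridged_cliques(self):
        net = self._two_bridged_cliques_network()
        filtered = filter_small({u: 0 for u in net.nodes}, min_size=5)
        subparts = repartition_communities(net, filtered, seed=1)
        final = subparts[0].final
        blocks = {frozenset(u for u in final if final[u] == c) for c in set(final.values())}
        assert blocks == {
            frozenset({"f0", "f1", "f2", "f3", "f4"}),
            frozenset({"f5", "f6", "f7", "f8", "f9"}),
        }

    def test_repartition_clique_stays_single(self):
        frags = FragmentSet(
            Fragment(f"f{i}", "chrI", i * 100, (i + 1) * 100) for i in range(5)
        )
        pairs = [(f"f{i}", f"f{j}", 0.001) for i in range(5) for j in range(i + 1, 5)]
        net = build_network(make_records(pairs, frags), frags, cls="complete")
        filtered = filter_small({u: 0 for u in net.nodes}, min_size=3)
        subparts = repartition_communities(net, filtered, seed=1)
        assert len(set(subparts[0].final.values())) == 1
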