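import itertools
import random

import pytest

from triplefocus import (
    PlantedConfig,
    build_graph,
    filter_communities,
    generate_planted_network,
    greedy_modularity_communities,
    modularity,
)
from triplefocus.graph import Graph

from .conftest import clique_edges, make_graph


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration, small inputs)."""
    if not items:
        yield []
        return
    head, *rest = items
    for partial in set_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [partial[i] | {head}] + partial[i + 1 :]
        yield partial + [{head}]


def best_partition_exhaustive(g):
    best_q, best = float("-inf"), None
    for part in set_partitions(sorted(g.nodes)):
        q = modularity(g, part)
        if q > best_q:
            best_q, best = q, part
    return best_q, best


class TestModularity:
    def test_single_community_is_zero(self, two_k3_bridged):
        assert modularity(two_k3_bridged, [set(two_k3_bridged.nodes)]) == (
            pytest.approx(0.0)
        )

    def test_two_k3_hand_value(self, two_k3_bridged):
        q = modularity(two_k3_bridged, [{"A", "B", "C"}, {"D", "E", "F"}])
        assert q == pytest.approx(5 / 14)

    def test_singletons_on_triangle(self):
        g = make_graph(clique_edges("ABC"))
        q = modularity(g, [{"A"}, {"B"}, {"C"}])
        assert q == pytest.approx(-1 / 3)

    def test_non_covering_partition_is_error(self, path3):
        with pytest.raises(ValueError):
            modularity(path3, [{"A", "B"}])
        with pytest.raises(ValueError):
            modularity(path3, [{"A", "B"}, {"B", "C"}])

    def test_edgeless_graph_is_error(self):
        g = make_graph([], extra_nodes=["A", "B"])
        with pytest.raises(ValueError):
            modularity(g, [{"A"}, {"B"}])

    def test_agrees_with_networkx_on_random_partitions(self):
        nx = pytest.importorskip("networkx")
        rng = random.Random(19)
        for _ in range(20):
            n = rng.randint(4, 10)
            g = Graph()
            names = [f"N{i}" for i in range(n)]
            for v in names:
                g.add_node(v)
            for u, v in itertools.combinations(names, 2):
                if rng.random() < 0.5:
                    g.add_edge(u, v)
            if g.m == 0:
                continue
            labels = [rng.randint(0, 2) for _ in names]
            part = [
                {v for v, l in zip(names, labels) if l == c} for c in set(labels)
            ]
            h = nx.Graph()
            h.add_nodes_from(names)
            h.add_edges_from(g.edges())
            assert modularity(g, part) == pytest.approx(
                nx.algorithms.community.modularity(h, part)
            )


class TestGreedy:
    def test_recovers_two_k4_cliques_exactly(self, two_k4_bridged):
        p = greedy_modularity_communities(two_k4_bridged)
        assert sorted(map(sorted, p.communities)) == [
            ["A", "B", "C", "D"], ["E", "F", "G", "H"],
        ]
        best_q, _ = best_partition_exhaustive(two_k4_bridged)
        assert p.q == pytest.approx(best_q)

    def test_triangle_stays_whole(self):
        g = make_graph(clique_edges("ABC"))
        p = greedy_modularity_communities(g)
        assert p.communities == [{"A", "B", "C"}]

    def test_never_beats_exhaustive_optimum_on_small_graphs(self):
        rng = random.Random(23)
        for _ in range(10):
            n = rng.randint(4, 7)
            g = Graph()
            names = [f"N{i}" for i in range(n)]
            for v in names:
                g.add_node(v)
            for u, v in itertools.combinations(names, 2):
                if rng.random() < 0.45:
                    g.add_edge(u, v)
            if g.m == 0:
                continue
            p = greedy_modularity_communities(g)
            best_q, _ = best_partition_exhaustive(g)
            assert p.q <= best_q + 1e-12

    def test_merge_gains_strictly_positive_and_q_above_singletons(
        self, planted_study
    ):
        records, *_ = planted_study
        g = build_graph(records)
        p = greedy_modularity_communities(g)
        assert all(gain > 0 for _, _, gain, _ in p.merge_log)
        singles_q = modularity(g, [{v} for v in g.nodes])
        assert p.q >= singles_q
        assert p.q == pytest.approx(modularity(g, p.communities))

    def test_invariant_to_node_insertion_order(self, two_k4_bridged):
        edges = two_k4_bridged.edges()
        p_ref = greedy_modularity_communities(two_k4_bridged)
        rng = random.Random(1)
        for _ in range(5):
            shuffled = edges[:]
            rng.shuffle(shuffled)
            g = Graph()
            for u, v in shuffled:
                g.add_edge(u, v)
            p = greedy_modularity_communities(g)
            assert p.communities == p_ref.communities
            assert p.q == pytest.approx(p_ref.q)

    def test_empty_graph_empty_partition(self):
        assert len(greedy_modularity_communities(Graph())) == 0

    def test_isolated_nodes_stay_singletons(self):
        g = make_graph(clique_edges("ABC"), extra_nodes=["X", "Y"])
        p = greedy_modularity_communities(g)
        assert {"X"} in p.communities and {"Y"} in p.communities

    def test_planted_blocks_recovered_on_one_seed(self):
        pytest.importorskip("sklearn")
        from sklearn.metrics import normalized_mutual_info_score

        cfg = PlantedConfig(seed=7)
        records, truth = generate_planted_network(cfg)
        nodes = truth.non_bridge_nodes
        g = build_graph(records, nodes)
        p = greedy_modularity_communities(g)
        nmi = normalized_mutual_info_score(
            [truth.block_of[v] for v in nodes], p.labels_for(nodes)
        )
        assert nmi >= 0.9


class TestFilterCommunities:
    def test_size_threshold(self):
        p = greedy_modularity_communities(
            make_graph(
                clique_edges([f"A{i}" for i in range(5)])
                + clique_edges([f"B{i}" for i in range(4)])
                + [("A0", "B0")],
                extra_nodes=["X"],
            )
        )
        kept = filter_communities(p, min_size=4)
        assert sorted(map(len, kept.communities)) == [4, 5]
        assert filter_communities(p, min_size=1).communities == p.communities

    def test_min_size_must_be_positive(self, two_k4_bridged):
        p = greedy_modularity_communities(two_k4_bridged)
        with pytest.raises(ValueError):
            filter_communities(p, 0)

    def test_planted_four_blocks_survive_default_filter(self, planted_study):
        records, _, _, _, _, truth = planted_study
        g = build_graph(records, truth.non_bridge_nodes)
        p = greedy_modularity_communities(g)
        kept = filter_communities(p, min_size=10)
        assert len(kept) == 4
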