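import networkx as nx
import numpy as np
import pytest

from coexnet import GeneSetCollection, hypergeom_enrich, louvain, modularity
from oracles import best_partition_q, brute_modularity, hypergeom_upper_tail


def graph(edges):
    g = nx.Graph()
    g.add_edges_from(edges)
    return g


TRIANGLES = graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])


class TestModularity:
    def test_two_disjoint_triangles_by_component(self):
        partition = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}
        assert modularity(TRIANGLES, partition) == pytest.approx(0.5)

    def test_single_community_is_zero(self):
        g = graph([(0, 1), (1, 2), (2, 3)])
        assert modularity(g, {v: 0 for v in g.nodes}) == pytest.approx(0.0)

    def test_singletons_on_single_edge(self):
        g = graph([("a", "b")])
        assert modularity(g, {"a": 0, "b": 1}) == pytest.approx(-0.5)

    def test_uncovered_node_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            modularity(TRIANGLES, {0: 0})

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_definition_on_random_partitions(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnm_random_graph(12, 25, seed=seed)
        partition = {v: int(rng.integers(3)) for v in g.nodes}
        assert modularity(g, partition) == pytest.approx(
            brute_modularity(g.edges, partition), abs=1e-12
        )


class TestLouvain:
    def test_two_triangles_with_bridge(self, two_triangles_bridge):
        part = louvain(two_triangles_bridge, seed=1)
        assert part.q == pytest.approx(5 / 14)
        assert len(part.sizes) == 2
        labels = part.labels
        assert labels["a"] == labels["b"] == labels["c"]
        assert labels["d"] == labels["e"] == labels["f"]
        # brute force over all partitions of 6 nodes confirms this is optimal
        assert part.q == pytest.approx(
            best_partition_q(two_triangles_bridge.edges, two_triangles_bridge.nodes)
        )

    def test_complete_graph_single_community(self):
        part = louvain(nx.complete_graph(5), seed=0)
        assert len(part.sizes) == 1
        assert part.q == pytest.approx(0.0)

    def test_disjoint_triangles(self):
        part = louvain(TRIANGLES, seed=0)
        assert len(part.sizes) == 2
        assert part.q == pytest.approx(0.5)
        assert part.q == pytest.approx(best_partition_q(TRIANGLES.edges, TRIANGLES.nodes))

    def test_reported_q_is_self_consistent(self, two_triangles_bridge):
        part = louvain(two_triangles_bridge, seed=3)
        assert part.q == pytest.approx(
            modularity(two_triangles_bridge, part.labels), abs=1e-12
        )

    def test_deterministic_given_seed(self):
        g = nx.gnm_random_graph(40, 120, seed=6)
        assert louvain(g, seed=9).labels == louvain(g, seed=9).labels

    @pytest.mark.parametrize("seed", range(5))
    def test_beats_almost_all_partitions_on_small_graphs(self, seed):
        g = nx.gnm_random_graph(8, 14, seed=seed)
        if g.number_of_edges() == 0:
            g.add_edge(0, 1)
        part = louvain(g, seed=seed)
        from oracles import all_partitions

        qs = sorted(
            brute_modularity(g.edges, {v: i for i, block in enumerate(blocks) for v in block})
            for blocks in all_partitions(list(g.nodes))
        )
        percentile_95 = qs[int(0.95 * (len(qs) - 1))]
        assert part.q >= percentile_95 - 1e-12

    def test_agrees_with_networkx_reference_on_modular_graph(self):
        # Independent cross-check: a planted 4-clique-of-cliques graph where the
        # optimum is unambiguous.
        g = nx.Graph()
        for c in range(4):
            members = [c * 6 + i for i in range(6)]
            g.add_edges_from(
                (u, v) for i, u in enumerate(members) for v in members[i + 1 :]
            )
        g.add_edges_from([(0, 6), (7, 12), (13, 18), (19, 1)])
        ours = louvain(g, seed=2)
        reference = nx.community.louvain_communities(g, seed=2)
        q_ref = nx.community.modularity(g, reference)
        assert ours.q == pytest.approx(q_ref, abs=1e-9)
        assert len(ours.sizes) == 4

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            louvain(nx.Graph(), seed=0)


class TestHypergeomEnrich:
    def make_partition(self, labels):
        from coexnet import ModulePartition

        return ModulePartition(labels=labels, q=0.0)

    def test_exact_tail_probabilities_match_enumeration(self):
        background = {f"g{i}" for i in range(10)}
        term_genes = frozenset({f"g{i}" for i in range(5)})
        sets = GeneSetCollection(sets={"T": ("term", term_genes)})
        for cluster_genes, k in [
            ({f"g{i}" for i in range(5)}, 5),  # complete overlap -> 1/252
            ({f"g{i}" for i in range(5, 10)}, 0),  # no overlap -> p = 1
            ({"g0", "g1", "g2", "g8", "g9"}, 3),  # partial -> ~0.5
        ]:
            labels = {g: (0 if g in cluster_genes else 1) for g in background}
            table = hypergeom_enrich(
                self.make_partition(labels), sets, background, min_cluster_size=5
            )
            row = table[(table["cluster"] == 0) & (table["term_id"] == "T")].iloc[0]
            assert row["k"] == k
            assert row["p"] == pytest.approx(hypergeom_upper_tail(10, 5, 5, k), rel=1e-12)
        assert hypergeom_upper_tail(10, 5, 5, 5) == pytest.approx(1 / 252)
        assert hypergeom_upper_tail(10, 5, 5, 0) == 1.0
        assert hypergeom_upper_tail(10, 5, 5, 3) == pytest.approx(0.5)

    def test_small_clusters_skipped(self):
        background = {f"g{i}" for i in range(10)}
        sets = GeneSetCollection(sets={"T": ("t", frozenset({"g0"}))})
        labels = {g: i for i, g in enumerate(sorted(background))}  # all singletons
        table = hypergeom_enrich(self.make_partition(labels), sets, background, 2)
        assert table.empty

    def test_gene_outside_background_rejected(self):
        sets = GeneSetCollection(sets={"T": ("t", frozenset({"g0"}))})
        with pytest.raises(ValueError, match="background"):
            hypergeom_enrich(self.make_partition({"g0": 0, "gX": 0}), sets, {"g0"}, 1)

    def test_empty_background_rejected(self):
        sets = GeneSetCollection(sets={"T": ("t", frozenset({"g0"}))})
        with pytest.raises(ValueError, match="background"):
            hypergeom_enrich(self.make_partition({}), sets, set(), 1)

    def test_bh_adjustment_monotone_in_p(self):
        background = {f"g{i}" for i in range(20)}
        sets = GeneSetCollection(
            sets={
                "T1": ("a", frozenset({f"g{i}" for i in range(10)})),
                "T2": ("b", frozenset({"g0", "g19"})),
            }
        )
        labels = {g: (0 if int(g[1:]) < 10 else 1) for g in background}
        table = hypergeom_enrich(self.make_partition(labels), sets, background, 5)
        assert (table["p_adj"] >= table["p"] - 1e-15).all()
        assert table["p"].is_monotonic_increasing
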