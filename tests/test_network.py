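"""RBH graph, MCL, hypergeometric significance and virus clustering."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from provirome.network import (
    STATUS_FRAGMENT,
    STATUS_KNOWN,
    STATUS_NEW,
    GenomeProfile,
    SequenceMeta,
    SimilarityHit,
    build_genome_network,
    build_rbh_graph,
    classify_vcs,
    cluster_genomes,
    genome_profiles,
    iccc,
    mcl,
    pair_significance,
    protein_clusters,
    sweep_parameters,
)


def hit(q, s, score, evalue=1e-20):
    return SimilarityHit(q, s, score, evalue)


class TestRbhGraph:
    def test_mutual_best_hit_edge_with_mean_weight(self):
        g = build_rbh_graph([hit("p", "q", 210), hit("q", "p", 190)])
        assert g.has_edge("p", "q")
        assert g["p"]["q"]["weight"] == 200.0

    def test_non_reciprocal_best_no_edge(self):
        g = build_rbh_graph(
            [hit("p", "q", 150), hit("q", "p", 150), hit("q", "r", 180),
             hit("r", "q", 180)]
        )
        assert not g.has_edge("p", "q")
        assert g.has_edge("q", "r")

    def test_low_score_excluded_before_best_selection(self):
        # p's only passing hit is r; the better-scoring q hit fails the cutoff
        g = build_rbh_graph(
            [hit("p", "q", 40), hit("q", "p", 40), hit("p", "r", 60),
             hit("r", "p", 60)]
        )
        assert not g.has_edge("p", "q")
        assert g.has_edge("p", "r")

    def test_evalue_threshold_applies(self):
        g = build_rbh_graph([hit("p", "q", 100, 0.5), hit("q", "p", 100, 0.5)])
        assert g.number_of_edges() == 0

    def test_empty_table_empty_graph(self):
        assert build_rbh_graph([]).number_of_nodes() == 0

    def test_per_genome_best_hits_connect_families(self):
        # q and r live in different genomes: p keeps a best hit in each
        hits = [
            hit("p", "q", 200), hit("q", "p", 200),
            hit("p", "r", 150), hit("r", "p", 150),
            hit("q", "r", 120), hit("r", "q", 120),
        ]
        mapping = {"p": "g1", "q": "g2", "r": "g3"}
        g = build_rbh_graph(hits, protein_to_genome=mapping)
        assert g.number_of_edges() == 3
        g_global = build_rbh_graph(hits)
        assert g_global.number_of_edges() == 1  # only the mutual global best


class TestMcl:
    def test_isolated_node_is_singleton(self):
        g = nx.Graph()
        g.add_node("solo")
        assert mcl(g) == [frozenset({"solo"})]

    def test_two_triangles_with_weak_bridge_split(self):
        g = nx.Graph()
        for a, b in itertools.combinations((0, 1, 2), 2):
            g.add_edge(a, b, weight=1.0)
        for a, b in itertools.combinations((3, 4, 5), 2):
            g.add_edge(a, b, weight=1.0)
        g.add_edge(2, 3, weight=0.1)
        clusters = mcl(g, inflation=2.0)
        assert sorted(map(sorted, clusters)) == [[0, 1, 2], [3, 4, 5]]

    @pytest.mark.parametrize("inflation", [1.5, 2.0, 4.0])
    def test_complete_graph_stays_one_cluster(self, inflation):
        g = nx.complete_graph(4)
        nx.set_edge_attributes(g, 1.0, "weight")
        assert len(mcl(g, inflation=inflation)) == 1

    def test_output_is_a_partition(self, default_world):
        g = build_rbh_graph(
            default_world.similarity,
            protein_to_genome=default_world.protein_to_virus(),
        )
        clusters = mcl(g, inflation=2.0)
        nodes = [n for c in clusters for n in c]
        assert len(nodes) == len(set(nodes)) == g.number_of_nodes()

    def test_negative_weight_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=-1.0)
        with pytest.raises(ValueError):
            mcl(g)

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError):
            mcl(nx.complete_graph(3), inflation=1.0)


def hypergeom_tail_enumeration(a, b, c, n):
    """Oracle: exact tail by summing the combinatorial formula."""
    return sum(
        math.comb(a, i) * math.comb(n - a, b - i) / math.comb(n, b)
        for i in range(c, min(a, b) + 1)
    )


class TestPairSignificance:
    def test_hand_case_third(self):
        sig = pair_significance(4, 3, 2, 10, n_pairs=1)
        assert sig.p == pytest.approx(40 / 120, abs=1e-12)
        assert sig.s == pytest.approx(-math.log10(40 / 120), abs=1e-9)

    def test_no_shared_pcs_is_null(self):
        sig = pair_significance(5, 4, 0, 20)
        assert sig.p == 1.0 and sig.s == 0.0

    def test_matches_enumeration_small_universe(self):
        for n in (4, 8, 12):
            for a in range(n + 1):
                for b in range(a + 1):
                    for c in range(b + 1):
                        expect = hypergeom_tail_enumeration(a, b, c, n)
                        assert pair_significance(a, b, c, n).p == pytest.approx(
                            expect, abs=1e-10
                        ), (a, b, c, n)

    def test_matches_monte_carlo_medium_universe(self):
        rng = np.random.default_rng(0)
        for a, b, c, n in ((18, 15, 6, 40), (25, 20, 14, 40), (10, 9, 3, 33)):
            draws = rng.hypergeometric(a, n - a, b, size=10**6)
            est = (draws >= c).mean()
            se = math.sqrt(max(est * (1 - est), 1e-12) / 10**6)
            assert abs(pair_significance(a, b, c, n).p - est) <= 3 * se + 1e-9

    def test_p_monotone_decreasing_in_shared_count(self):
        ps = [pair_significance(10, 8, c, 30).p for c in range(9)]
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_counts_exceeding_universe_rejected(self):
        with pytest.raises(ValueError):
            pair_significance(12, 5, 2, 10)


class TestGenomeNetwork:
    def profiles(self):
        return {
            "A": GenomeProfile("A", frozenset({"p1", "p2", "p3"}), 5),
            "B": GenomeProfile("B", frozenset({"p1", "p2", "p4"}), 5),
            "C": GenomeProfile("C", frozenset({"p5"}), 2),
        }

    def test_no_shared_pcs_no_edge(self):
        g = build_genome_network(self.profiles(), sig_threshold=0.0)
        assert not g.has_edge("A", "C")

    def test_threshold_filters_weak_pairs(self):
        profiles = self.profiles()
        weak = build_genome_network(profiles, sig_threshold=10.0)
        assert weak.number_of_edges() == 0

    def test_raising_threshold_never_adds_edges(self):
        profiles = self.profiles()
        e1 = set(build_genome_network(profiles, sig_threshold=0.0).edges)
        e2 = set(build_genome_network(profiles, sig_threshold=1.0).edges)
        assert e2 <= e1

    def test_profile_invariant(self):
        with pytest.raises(ValueError):
            GenomeProfile("X", frozenset({"p1", "p2"}), 1)


class TestIccc:
    def test_all_intra_cluster_edges_give_one(self):
        g = nx.complete_graph(4)
        assert iccc(g, [frozenset(range(4))]) == 1.0

    def test_singleton_clusters_give_zero(self):
        g = nx.path_graph(4)
        assert iccc(g, [frozenset({n}) for n in g.nodes]) == 0.0

    def test_half_coclustered_neighbors(self):
        g = nx.Graph([("a", "b"), ("a", "c")])
        clusters = [frozenset({"a", "b"}), frozenset({"c"})]
        # a: 1/2, b: 1/1, c: 0/1 -> mean 0.5
        assert iccc(g, clusters) == pytest.approx(0.5)

    def test_edgeless_graph_undefined(self):
        g = nx.empty_graph(3)
        with pytest.raises(ValueError):
            iccc(g, [frozenset({n}) for n in g.nodes])


class TestClusterRecovery:
    def test_true_genera_recovered(self, default_world):
        """Protein families and virus genera recovered at ARI >= 0.9."""
        world = default_world
        prot2seq = world.protein_to_virus()
        pcs = protein_clusters(world.similarity, protein_to_genome=prot2seq)
        pc_of = {p: pc for pc, members in pcs.items() for p in members}
        fams = world.truth.protein_family
        ari_prot = adjusted_rand_score(
            [fams[p] for p in fams], [pc_of.get(p, f"s_{p}") for p in fams]
        )
        assert ari_prot >= 0.9

        profiles = genome_profiles(pcs, prot2seq, world.gene_counts())
        network = build_genome_network(profiles, sig_threshold=1.0)
        clusters, unclustered = cluster_genomes(network, inflation=4.0)
        assert len(unclustered) / len(profiles) <= 0.05
        cl_of = {m: i for i, c in enumerate(clusters) for m in c}
        truth = world.truth.virus_cluster
        ari_vc = adjusted_rand_score(
            [truth[v] for v in truth], [cl_of.get(v, f"u_{v}") for v in truth]
        )
        assert ari_vc >= 0.9

    def test_disconnected_cliques_form_two_vcs(self):
        g = nx.Graph()
        for a, b in itertools.combinations("abc", 2):
            g.add_edge(a, b, weight=1.0)
        for a, b in itertools.combinations("xyz", 2):
            g.add_edge(a, b, weight=1.0)
        clusters, unclustered = cluster_genomes(g)
        assert len(clusters) == 2 and not unclustered


class TestSweep:
    def test_single_cell_grid_returns_it(self, default_world):
        world = default_world
        prot2seq = world.protein_to_virus()
        pcs = protein_clusters(world.similarity, protein_to_genome=prot2seq)
        profiles = genome_profiles(pcs, prot2seq, world.gene_counts())
        table, best = sweep_parameters(profiles, thresholds=(1,), inflations=(2.0,))
        assert len(table) == 1
        assert best["threshold"] == 1.0 and best["inflation"] == 2.0

    def test_argmax_at_lowest_threshold(self, default_world):
        """Cluster homogeneity is best at the most permissive threshold."""
        world = default_world
        prot2seq = world.protein_to_virus()
        pcs = protein_clusters(world.similarity, protein_to_genome=prot2seq)
        profiles = genome_profiles(pcs, prot2seq, world.gene_counts())
        thresholds = (1, 5, 10, 20, 30, 40, 50)
        table, best = sweep_parameters(
            profiles, thresholds=thresholds, inflations=(2.0, 3.0, 4.0, 5.0)
        )
        assert best["threshold"] == min(thresholds)

    def test_clusters_do_not_decrease_with_inflation(self, default_world):
        world = default_world
        prot2seq = world.protein_to_virus()
        pcs = protein_clusters(world.similarity, protein_to_genome=prot2seq)
        profiles = genome_profiles(pcs, prot2seq, world.gene_counts())
        table, _ = sweep_parameters(
            profiles, thresholds=(1,), inflations=(1.5, 2.5, 3.5, 4.5)
        )
        counts = table.sort_values("inflation")["n_clusters"].tolist()
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_empty_grid_rejected(self, default_world):
        with pytest.raises(ValueError):
            sweep_parameters({}, thresholds=())


class TestClassifyVcs:
    META = {
        "circ": SequenceMeta(circular=True, length_bp=8_000),
        "ref": SequenceMeta(complete=True, length_bp=50_000, is_reference=True),
        "frag1": SequenceMeta(length_bp=15_000),
        "frag2": SequenceMeta(length_bp=15_000),
        "frag3": SequenceMeta(length_bp=15_000),
        "big": SequenceMeta(length_bp=45_000),
    }

    def test_circular_member_without_reference_is_new_genus(self):
        vcs, counts = classify_vcs([frozenset({"circ", "frag1"})], self.META)
        assert vcs[0].status == STATUS_NEW
        assert counts["n_new"] == 1

    def test_reference_member_makes_known_genus(self):
        vcs, _ = classify_vcs([frozenset({"ref", "big"})], self.META)
        assert vcs[0].status == STATUS_KNOWN

    def test_short_fragments_never_called_genus(self):
        vcs, counts = classify_vcs(
            [frozenset({"frag1", "frag2", "frag3"})], self.META
        )
        assert vcs[0].status == STATUS_FRAGMENT
        assert counts["n_putative_genera"] == 0

    def test_missing_metadata_names_sequence(self):
        with pytest.raises(ValueError, match="ghost"):
            classify_vcs([frozenset({"ghost"})], self.META)
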