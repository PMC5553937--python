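import string

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrnet import (
    betweenness,
    build_network,
    cluster_dominant_gene,
    clustered_node_count,
    clusters,
    degree,
    edge_count,
    export_graph,
    levenshtein,
    network_from_repertoire,
    within_distance_one,
)
from tcrnet.network import DeletionVariantIndex, import_graphml, node_attribute_table

from oracles import all_pairs_distance1_edges, dp_levenshtein

AA = "ACDEFGHIKLMNPQRSTVWY"
aa_strings = st.text(alphabet=AA, min_size=1, max_size=16)


class TestDistancePredicate:
    def test_identical_is_not_distance_one(self):
        assert not within_distance_one("CASSLG", "CASSLG")

    def test_single_substitution(self):
        assert within_distance_one("CASS", "CAST")

    def test_single_insertion(self):
        assert within_distance_one("CASSLG", "CASSLLG")

    def test_length_gap_two_is_false(self):
        assert not within_distance_one("CA", "CASS")

    def test_empty_string_errors(self):
        with pytest.raises(ValueError):
            within_distance_one("", "CASS")
        with pytest.raises(ValueError):
            levenshtein("CASS", "")

    def test_predicate_matches_dp_oracle_on_random_pairs(self, rng):
        for _ in range(2000):
            a = "".join(rng.choice(list(AA[:6]), size=rng.integers(8, 21)))
            b = "".join(rng.choice(list(AA[:6]), size=rng.integers(8, 21)))
            assert within_distance_one(a, b) == (dp_levenshtein(a, b) == 1)

    @given(a=aa_strings, b=aa_strings)
    @settings(max_examples=200, deadline=None)
    def test_levenshtein_agrees_with_oracle(self, a, b):
        assert levenshtein(a, b) == dp_levenshtein(a, b)

    @given(a=aa_strings, b=aa_strings)
    @settings(max_examples=200, deadline=None)
    def test_predicate_agrees_with_distance(self, a, b):
        assert within_distance_one(a, b) == (levenshtein(a, b) == 1)


class TestBuildNetwork:
    def test_three_node_path(self):
        net = build_network({"CASS", "CAST", "CATT"})
        assert set(map(frozenset, net.edges)) == {
            frozenset({"CASS", "CAST"}), frozenset({"CAST", "CATT"})}
        cl = clusters(net)
        assert len(cl) == 1 and len(cl[0]) == 3 and cl[0].edge_count == 2

    def test_empty_input(self):
        net = build_network(set())
        assert net.number_of_nodes() == 0 and edge_count(net) == 0

    def test_duplicate_input_errors(self):
        with pytest.raises(ValueError):
            build_network(["CASS", "CASS"])

    def test_matches_all_pairs_oracle_on_mutation_pool(self, rng):
        pool = ["".join(rng.choice(list(AA), size=12)) for _ in range(30)]
        seqs = set(pool)
        for base in pool:
            for _ in range(5):
                pos = rng.integers(len(base))
                seqs.add(base[:pos] + rng.choice(list(AA)) + base[pos + 1:])
        net = build_network(seqs)
        assert set(tuple(sorted(e)) for e in net.edges) == all_pairs_distance1_edges(seqs)

    def test_deletion_index_neighbors_match_scan(self, rng):
        seqs = ["".join(rng.choice(list(AA[:4]), size=rng.integers(3, 7)))
                for _ in range(200)]
        seqs = list(set(seqs))
        index = DeletionVariantIndex(seqs)
        probe = seqs[0]
        expected = {s for s in seqs if s != probe and dp_levenshtein(probe, s) == 1}
        assert index.neighbors(probe) == expected

    def test_symmetry_degree_sum(self, small_repertoire):
        from tcrnet import top_n

        net = build_network(top_n(small_repertoire, 400).sequences)
        assert sum(degree(net).values()) == 2 * edge_count(net)

    def test_monotone_under_node_addition(self):
        base = {"CASS", "CAST"}
        net1 = build_network(base)
        net2 = build_network(base | {"CATT", "WWWW"})
        assert set(net1.edges) <= set(net2.edges)
        assert clustered_node_count(net2) >= clustered_node_count(net1)


class TestClusters:
    def test_path_plus_isolated(self):
        net = build_network({"AAAA", "AAAC", "AACC", "WWWWWWW"})
        cl = clusters(net)
        assert len(cl) == 1
        assert cl[0].members == frozenset({"AAAA", "AAAC", "AACC"})
        assert clustered_node_count(net) == 3
        assert "WWWWWWW" in net.nodes

    def test_fully_disconnected(self):
        seqs = {"A" * k for k in range(2, 30, 3)}
        net = build_network(seqs)
        assert clusters(net) == []
        assert clustered_node_count(net) == 0

    def test_clusters_partition_non_isolated_nodes(self, small_repertoire):
        from tcrnet import top_n

        net = build_network(top_n(small_repertoire, 500).sequences)
        cls = clusters(net)
        members = [m for c in cls for m in c.members]
        assert len(members) == len(set(members))
        non_isolated = {n for n, d in net.degree() if d > 0}
        assert set(members) == non_isolated


class TestCentrality:
    def test_path_betweenness(self):
        net = build_network({"AAAA", "AAAC", "AACC"})
        btw = betweenness(net)
        deg = degree(net)
        assert deg["AAAC"] == 2
        assert btw["AAAC"] == pytest.approx(1.0)
        assert btw["AAAA"] == pytest.approx(0.0)

    def test_isolated_node(self):
        net = build_network({"AAAA", "WWWWWWW"})
        assert degree(net)["WWWWWWW"] == 0
        assert betweenness(net)["WWWWWWW"] == pytest.approx(0.0)

    @pytest.mark.parametrize("k", [3, 5, 8])
    def test_star_closed_form(self, k):
        center = "A" * 10
        leaves = {center[:i] + "W" + center[i + 1:] for i in range(k)}
        net = build_network(leaves | {center})
        # leaves may connect to each other at distance 2? no: two
        # substitutions apart, so the graph is an exact star
        assert degree(net)[center] == k
        assert betweenness(net)[center] == pytest.approx(k * (k - 1) / 2)

    def test_normalized_option(self):
        net = build_network({"AAAA", "AAAC", "AACC"})
        raw = betweenness(net, normalized=False)
        norm = betweenness(net, normalized=True)
        assert norm["AAAC"] == pytest.approx(raw["AAAC"] / 1.0)  # (n-1)(n-2)/2 = 1


class TestDominantGene:
    def test_uniform_cluster(self):
        net = build_network(
            {"CASSF", "CASTF"},
            attributes={"CASSF": {"j_usage": {"TRBJ2-7": 6}},
                        "CASTF": {"j_usage": {"TRBJ2-7": 3}}},
        )
        gene, frac = cluster_dominant_gene(net, clusters(net)[0], "J")
        assert gene == "TRBJ2-7" and frac == pytest.approx(1.0)

    def test_mixed_cluster_fraction(self, toy_repertoire):
        net = network_from_repertoire(toy_repertoire)
        cl = [c for c in clusters(net) if "CASSF" in c.members][0]
        gene, frac = cluster_dominant_gene(net, cl, "J")
        assert gene == "TRBJ2-7" and frac == pytest.approx(9 / 10)

    def test_mixed_tallies(self):
        net = build_network(
            {"CASS", "CAST"},
            attributes={"CASS": {"j_usage": {"J1": 3}}, "CAST": {"j_usage": {"J2": 5}}},
        )
        cl = clusters(net)[0]
        gene, frac = cluster_dominant_gene(net, cl, "J")
        assert gene == "J2" and frac == pytest.approx(5 / 8)

    def test_missing_usage_errors(self):
        net = build_network({"CASS", "CAST"})
        with pytest.raises(ValueError):
            cluster_dominant_gene(net, clusters(net)[0], "J")

    def test_j_homogeneity_exceeds_v_on_simulated_network(self, small_repertoire):
        from tcrnet import top_n

        net = network_from_repertoire(top_n(small_repertoire, 600))
        cls = [c for c in clusters(net) if len(c) >= 3]
        assert cls, "expected some clusters of size >= 3"
        j_frac = np.mean([cluster_dominant_gene(net, c, "J")[1] for c in cls])
        v_frac = np.mean([cluster_dominant_gene(net, c, "V")[1] for c in cls])
        assert j_frac > v_frac


class TestExport:
    def test_graphml_round_trip(self, tmp_path, toy_repertoire):
        net = network_from_repertoire(toy_repertoire)
        path = tmp_path / "net.graphml"
        export_graph(net, path, format="graphml")
        back = import_graphml(path)
        assert set(back.nodes) == set(net.nodes)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, net.edges))

    def test_graphml_element_counts(self, tmp_path):
        net = build_network({"CASS", "CAST", "CATT"})
        path = tmp_path / "net.graphml"
        export_graph(net, path)
        text = path.read_text()
        assert text.count("<node ") == 3
        assert text.count("<edge ") == 2

    def test_sif_lists_edges_and_singletons(self, tmp_path):
        net = build_network({"CASS", "CAST", "WWWWWWW"})
        path = tmp_path / "net.sif"
        export_graph(net, path, format="sif")
        lines = path.read_text().strip().splitlines()
        assert "CASS\tld1\tCAST" in lines
        assert "WWWWWWW" in lines

    def test_attribute_table_row_count(self, tmp_path, toy_repertoire):
        net = network_from_repertoire(toy_repertoire)
        path = tmp_path / "nodes.csv"
        rows = node_attribute_table(net, path)
        assert len(rows) == net.number_of_nodes()
        assert len(path.read_text().strip().splitlines()) == len(rows) + 1
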