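"""Anti-correlation edge filtering, bipartite construction, hub ranking and
network merging."""

import networkx as nx
import pandas as pd
import pytest

from trfnet import network as net

from _oracles import cross_join_pair_filter


def _de(rows):
    """rows: {id: (direction, p, fc)}"""
    return pd.DataFrame(
        {"direction": {k: v[0] for k, v in rows.items()},
         "p_value": {k: v[1] for k, v in rows.items()},
         "fold_change": {k: v[2] for k, v in rows.items()}})


DE_SNC = _de({"miR-1": ("up", 0.001, 2.0), "miR-2": ("down", 0.01, 0.4),
              "miR-3": ("up", 0.02, 1.5), "miR-4": ("ns", 0.5, 1.1)})
DE_MRNA = _de({"Fos": ("down", 0.001, 0.3), "Mybl1": ("up", 0.002, 3.0),
               "Gene1": ("down", 0.03, 0.45), "Gene2": ("ns", 0.9, 1.0),
               "Gene3": ("up", 0.04, 2.5)})


def _pairs(items):
    return pd.DataFrame(items, columns=["sncrna", "mrna", "best_score"])


class TestPairFilter:
    def test_anticorrelated_kept(self):
        edges = net.pair_filter(DE_SNC, DE_MRNA,
                                _pairs([("miR-1", "Fos", 150.0)]))
        assert len(edges) == 1
        assert edges[0].regulator_direction == "up"
        assert edges[0].target_direction == "down"

    def test_same_direction_rejected(self):
        assert net.pair_filter(DE_SNC, DE_MRNA,
                               _pairs([("miR-1", "Mybl1", 150.0)])) == []

    def test_ns_features_never_appear(self):
        edges = net.pair_filter(DE_SNC, DE_MRNA,
                                _pairs([("miR-4", "Fos", 150.0),
                                        ("miR-1", "Gene2", 150.0)]))
        assert edges == []

    def test_hand_counted_toy(self):
        # 3 regulators x 2 anti-correlated targets each
        items = [(s, m, 141.0) for s in ("miR-1", "miR-3") for m in
                 ("Fos", "Gene1")] + \
                [("miR-2", m, 141.0) for m in ("Mybl1", "Gene3")]
        edges = net.pair_filter(DE_SNC, DE_MRNA, _pairs(items))
        assert len(edges) == 6

    def test_matches_cross_join_oracle(self):
        all_pairs = _pairs([(s, m, 150.0) for s in DE_SNC.index
                            for m in DE_MRNA.index])
        edges = net.pair_filter(DE_SNC, DE_MRNA, all_pairs)
        got = sorted((e.regulator, e.target) for e in edges)
        assert got == cross_join_pair_filter(DE_SNC, DE_MRNA, all_pairs)

    def test_unknown_ids_logged_and_dropped(self, caplog):
        with caplog.at_level("WARNING"):
            edges = net.pair_filter(DE_SNC, DE_MRNA,
                                    _pairs([("miR-99", "Fos", 150.0)]))
        assert edges == []
        assert "miR-99" in caplog.text

    def test_subset_of_predictions(self):
        all_pairs = _pairs([(s, m, 150.0) for s in DE_SNC.index
                            for m in DE_MRNA.index])
        edges = net.pair_filter(DE_SNC, DE_MRNA, all_pairs)
        predicted = set(zip(all_pairs["sncrna"], all_pairs["mrna"]))
        assert {(e.regulator, e.target) for e in edges} <= predicted


def _toy_graph(tfs=("Fos",)):
    items = [(s, m, 141.0) for s in ("miR-1", "miR-3") for m in
             ("Fos", "Gene1")] + \
            [("miR-2", m, 141.0) for m in ("Mybl1", "Gene3")]
    edges = net.pair_filter(DE_SNC, DE_MRNA, _pairs(items))
    return net.build_network(edges, DE_SNC, DE_MRNA, tfs, "miRNA")


class TestBuildNetwork:
    def test_degrees_match_incidence(self):
        g = _toy_graph()
        for reg in ("miR-1", "miR-2", "miR-3"):
            assert g.nodes[reg]["degree"] == 2
        assert g.nodes["Fos"]["degree"] == 2

    def test_degree_sum_is_twice_edges(self):
        g = _toy_graph()
        assert sum(d for _, d in g.degree()) == 2 * g.number_of_edges()

    def test_tf_annotation(self):
        g = _toy_graph(tfs=("Fos", "Mybl1"))
        assert g.nodes["Fos"]["is_tf"] and g.nodes["Mybl1"]["is_tf"]
        assert not g.nodes["Gene1"]["is_tf"]
        assert not g.nodes["miR-1"]["is_tf"]

    def test_empty_edge_set(self):
        g = net.build_network([], DE_SNC, DE_MRNA)
        assert g.number_of_nodes() == 0

    def test_bipartite_violation_rejected(self):
        bad = net.RegulatoryEdge("Fos", "Gene1", "up", "down", 150.0)
        de_fake = DE_MRNA.copy()
        with pytest.raises(ValueError):
            net.build_network(
                [bad, net.RegulatoryEdge("miR-1", "Fos", "up", "down", 150.0)],
                de_fake, DE_MRNA)

    def test_edge_requires_opposite_directions(self):
        with pytest.raises(ValueError, match="opposite"):
            net.RegulatoryEdge("miR-1", "Fos", "up", "up", 150.0)


class TestHubRanking:
    def test_planted_hub_first(self):
        de_snc = _de({f"m{i}": ("up", 0.01, 2.0) for i in range(5)})
        de_m = _de({f"G{i}": ("down", 0.01, 0.4) for i in range(10)})
        items = [(f"m0", f"G{i}", 150.0) for i in range(10)]
        items += [(f"m{j}", f"G{j}", 150.0) for j in range(1, 4)]
        g = net.build_network(net.pair_filter(de_snc, de_m, _pairs(items)),
                              de_snc, de_m)
        assert net.hub_ranking(g, 3)[0] == "m0"

    def test_p_value_breaks_degree_ties(self):
        de_snc = _de({"a": ("up", 0.01, 2.0), "b": ("up", 0.001, 2.0)})
        de_m = _de({"G1": ("down", 0.01, 0.4), "G2": ("down", 0.01, 0.4)})
        items = [("a", "G1", 150.0), ("b", "G2", 150.0)]
        g = net.build_network(net.pair_filter(de_snc, de_m, _pairs(items)),
                              de_snc, de_m)
        assert net.hub_ranking(g, 2) == ["b", "a"]

    def test_k_larger_than_regulators(self):
        g = _toy_graph()
        assert len(net.hub_ranking(g, 100)) == 3

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            net.hub_ranking(_toy_graph(), 0)


class TestTfOverlap:
    def test_fixture_sets_overlap(self):
        # the two six-TF sets of the miRNA and tRF/tiRNA networks
        set_a = ["Mybl1", "Fos", "Giot1", "Arid4b", "Zfp347", "Gabpa"]
        set_b = ["Mybl1", "Fos", "Nr4a1", "Pbrm1", "Lin28a", "Gabpa"]
        de_m = _de({g: ("down", 0.01, 0.4) for g in set(set_a + set_b)})
        de_s = _de({"r1": ("up", 0.01, 2.0)})
        ga = net.build_network(
            net.pair_filter(de_s, de_m,
                            _pairs([("r1", g, 150.0) for g in set_a])),
            de_s, de_m, tf_list=set_a)
        gb = net.build_network(
            net.pair_filter(de_s, de_m,
                            _pairs([("r1", g, 150.0) for g in set_b])),
            de_s, de_m, tf_list=set_b, regulator_type="tRF/tiRNA")
        assert net.tf_overlap(ga, gb) == {"Mybl1", "Fos", "Gabpa"}

    def test_disjoint_and_identical(self):
        g = _toy_graph(tfs=("Fos",))
        h = _toy_graph(tfs=())
        assert net.tf_overlap(g, h) == set()
        assert net.tf_overlap(g, g) == {"Fos"}

    def test_default_fixture_contains_both_six_tf_sets(self):
        tfs = net.default_tf_list()
        assert {"Mybl1", "Fos", "Giot1", "Arid4b", "Zfp347", "Gabpa"} <= tfs
        assert {"Nr4a1", "Pbrm1", "Lin28a"} <= tfs


class TestMergeNetworks:
    def test_shared_mrna_degree_sums(self):
        de_s1 = _de({"m1": ("up", 0.01, 2.0)})
        de_s2 = _de({"t1": ("up", 0.01, 2.0)})
        de_m = _de({"Fos": ("down", 0.01, 0.3)})
        g1 = net.build_network(
            net.pair_filter(de_s1, de_m, _pairs([("m1", "Fos", 150.0)])),
            de_s1, de_m)
        g2 = net.build_network(
            net.pair_filter(de_s2, de_m, _pairs([("t1", "Fos", 150.0)])),
            de_s2, de_m, regulator_type="tRF/tiRNA")
        merged = net.merge_networks(g1, g2)
        assert merged.nodes["Fos"]["degree"] == 2
        assert merged.number_of_edges() == 2

    def test_disjoint_graphs_additive(self):
        de_s = _de({"m1": ("up", 0.01, 2.0), "t1": ("up", 0.01, 2.0)})
        de_m = _de({"G1": ("down", 0.01, 0.4), "G2": ("down", 0.01, 0.4)})
        g1 = net.build_network(
            net.pair_filter(de_s, de_m, _pairs([("m1", "G1", 150.0)])),
            de_s, de_m)
        g2 = net.build_network(
            net.pair_filter(de_s, de_m, _pairs([("t1", "G2", 150.0)])),
            de_s, de_m, regulator_type="tRF/tiRNA")
        merged = net.merge_networks(g1, g2)
        assert merged.number_of_nodes() == 4

    def test_self_merge_idempotent(self):
        g = _toy_graph()
        merged = net.merge_networks(g, g)
        assert nx.utils.graphs_equal(merged, g)

    def test_conflicting_attributes_rejected(self):
        g = _toy_graph(tfs=("Fos",))
        h = _toy_graph(tfs=())
        with pytest.raises(ValueError, match="Fos"):
            net.merge_networks(g, h)


class TestExport:
    def test_sif_format(self, tmp_path):
        g = _toy_graph()
        p = tmp_path / "net.sif"
        net.write_sif(g, p)
        lines = p.read_text().splitlines()
        assert len(lines) == g.number_of_edges()
        for line in lines:
            reg, rel, tgt = line.split("\t")
            assert rel == "targets"
            assert g.nodes[reg]["node_type"] == "miRNA"
            assert g.nodes[tgt]["node_type"] == "mRNA"

    def test_graphml_round_trip(self, tmp_path):
        g = _toy_graph()
        p = tmp_path / "net.graphml"
        net.write_graphml(g, p)
        back = nx.read_graphml(p)
        assert set(back.nodes) == set(g.nodes)
        assert back.nodes["miR-1"]["node_type"] == "miRNA"
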