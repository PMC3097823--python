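import numpy as np
import pytest
from scipy.stats import spearmanr

from helpers import bfs_mean_path, row_of
from mlnet.core_model import BOR1, BOR15, InventoryProfile, PAPMatrix
from mlnet.mln import (
    LateralNetwork,
    build_mln,
    classify_edges,
    degree_stats,
    edge_weight_histogram,
    graph_stats,
    group_edge_analysis,
    recent_borrowing_fraction,
    validate_known_borrowings,
)
from mlnet.dataio import parse_newick
from mlnet.origin_loss import infer_BORk, infer_scenarios
from mlnet.simulate import random_yule_tree, simulate_pap


def _pap(tree, rows):
    return PAPMatrix(
        [f"c{i}" for i in range(len(rows))],
        list(tree.taxa),
        np.stack([row_of(tree, r) for r in rows]),
    )


def _mln(tree, rows, model=BOR1):
    return build_mln(tree, infer_scenarios(tree, _pap(tree, rows), model))


class TestBuild:
    def test_single_patchy_character(self, t4):
        net = _mln(t4, ["1010"])
        assert net.weights == {(t4.node("A"), t4.node("C")): 1}

    def test_weights_are_additive(self, t4):
        net = _mln(t4, ["1010", "1010"])
        assert net.weights[(t4.node("A"), t4.node("C"))] == 2
        assert net.edge_chars[(t4.node("A"), t4.node("C"))] == ["c0", "c1"]

    def test_single_origin_characters_give_empty_network(self, t4):
        net = _mln(t4, ["1100", "1111", "1000"])
        assert net.n_lateral_edges == 0

    def test_weight_conservation_on_simulated_data(self, rng):
        tree = random_yule_tree(16, rng)
        pap, _ = simulate_pap(tree, 150, 0.05, 1.0, rng)
        scenarios = infer_scenarios(tree, pap, BOR15)
        net = build_mln(tree, scenarios)
        assert net.total_lateral_weight == sum(s.n_borrowings for s in scenarios.values())


class TestDegreeStats:
    def test_single_edge(self, t4):
        conn, cmin, cmax, cmed = degree_stats(_mln(t4, ["1010"]))
        assert conn[t4.node("A")] == 1 and conn[t4.node("C")] == 1
        assert conn.sum() == 2 and cmin == 0 and cmax == 1 and cmed == 0

    def test_empty_network(self, t4):
        conn, cmin, cmax, cmed = degree_stats(_mln(t4, ["1111"]))
        assert not conn.any() and cmax == 0

    def test_multiplicity_ignored(self, t4):
        conn, *_ = degree_stats(_mln(t4, ["1010", "1010"]))
        assert conn[t4.node("A")] == 1  # two shared characters, one neighbour


class TestGraphStats:
    def test_pure_tree_is_triangle_free(self, t8):
        clustering, _ = graph_stats(_mln(t8, ["11111111"]))
        assert clustering == 0.0

    def test_triangle(self):
        tree = parse_newick("(A,B);")
        net = _mln(tree, ["11", "11", "10"])
        # add one lateral edge A-B by hand: union graph becomes a triangle
        net.weights[(tree.node("A"), tree.node("B"))] = 1
        clustering, mean_path = graph_stats(net)
        assert clustering == pytest.approx(1.0)
        assert mean_path == pytest.approx(1.0)

    def test_t4_with_sibling_lateral_edge(self, t4):
        net = _mln(t4, ["1111"])
        net.weights[(t4.node("A"), t4.node("B"))] = 1  # forms triangle A,B,N2
        clustering, mean_path = graph_stats(net)
        assert clustering == pytest.approx((1 + 1 + 1 / 3) / 7)
        edges = [(v, int(t4.parent[v])) for v in range(t4.n_nodes - 1)]
        edges.append((t4.node("A"), t4.node("B")))
        assert mean_path == pytest.approx(bfs_mean_path(edges, t4.n_nodes))


class TestEdgeHistogramAndKinds:
    def test_histogram(self, t4):
        net = _mln(t4, ["1010", "0101", "0101", "0101"])
        hist = edge_weight_histogram(net)
        assert hist == {1: 1, 3: 1}
        assert sum(hist.values()) == net.n_lateral_edges

    def test_empty_histogram(self, t4):
        assert edge_weight_histogram(_mln(t4, ["1111"])) == {}

    def test_edge_kind_classification(self, t8):
        net = _mln(t8, ["11111111"])
        a, c = t8.node("A"), t8.node("C")
        ab = t8.node("N2")   # internal ancestor of A,B
        ef = t8.node("N9")   # internal ancestor of E,F
        net.weights = {(a, c): 1, (min(a, ef), max(a, ef)): 1, (min(ab, ef), max(ab, ef)): 2}
        kinds = classify_edges(net)
        assert kinds == {
            "external-external": 1,
            "external-internal": 1,
            "internal-internal": 1,
        }
        assert sum(kinds.values()) == net.n_lateral_edges


class TestRecentBorrowing:
    def test_fraction_arithmetic(self, t4):
        sizes = np.zeros(t4.n_nodes, dtype=int)
        sizes[t4.leaf_ids] = [200, 10, 50, 7]
        a, c = t4.node("A"), t4.node("C")
        net = LateralNetwork(
            t4,
            InventoryProfile(t4, sizes),
            weights={(a, c): 2},
            edge_chars={(a, c): ["c1", "c2"]},
        )
        fractions, mean, sd = recent_borrowing_fraction(net)
        assert fractions["A"] == pytest.approx(1.0)   # 2 of 200
        assert fractions["B"] == 0.0
        assert 0 <= mean <= 100 and sd >= 0

    def test_zero_inventory_leaf_is_missing(self, t4):
        sizes = np.zeros(t4.n_nodes, dtype=int)
        sizes[t4.leaf_ids] = [5, 0, 5, 5]
        net = LateralNetwork(t4, InventoryProfile(t4, sizes))
        fractions, _, _ = recent_borrowing_fraction(net)
        assert fractions["B"] is None

    def test_heavily_borrowed_leaves_have_larger_fractions(self):
        # leaves that directly received more borrowing events get larger
        # recent-borrowing fractions (recent = lateral edge at the leaf)
        corrs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            tree = random_yule_tree(24, rng)
            pap, truth = simulate_pap(tree, 300, 0.05, 0.6, rng)
            net = build_mln(tree, infer_scenarios(tree, pap, BOR1))
            fractions, _, _ = recent_borrowing_fraction(net)
            hit = np.zeros(tree.n_leaves)
            for char in truth.chars:
                for b in char.borrowings:
                    if tree.is_leaf[b]:
                        hit[tree.leaf_lo[b]] += 1
            observed = np.array([fractions[t] for t in tree.taxa], dtype=float)
            corrs.append(spearmanr(hit, observed).statistic)
        assert np.median(corrs) > 0


class TestGroupAnalysis:
    def _net_with_edges(self, t8, edges):
        net = _mln(t8, ["11111111"])
        net.weights = {(min(a, b), max(a, b)): w for a, b, w in edges}
        return net

    def test_within_group_concentration(self, t8):
        groups = {t: ("west" if t in "ABCD" else "east") for t in t8.taxa}
        a, b, c = t8.node("A"), t8.node("B"), t8.node("C")
        e = t8.node("E")
        net = self._net_with_edges(t8, [(a, b, 2), (a, c, 2), (b, c, 3), (a, e, 1), (c, e, 1)])
        df = group_edge_analysis(net, groups).set_index("group")
        west = df.loc["west"]
        assert west["internal_edges"] == 3 and west["external_edges"] == 2
        assert west["median_internal_weight"] == 2.0
        assert west["median_external_weight"] == 1.0
        assert west["ks_p"] < 0.5
        east = df.loc["east"]
        assert east["internal_edges"] == 0 and east["external_edges"] == 2

    def test_edges_within_one_cherry_only(self, t4):
        groups = {"A": "g1", "B": "g1", "C": "g2", "D": "g2"}
        net = _mln(t4, ["1111"])
        net.weights = {(t4.node("A"), t4.node("B")): 1}
        df = group_edge_analysis(net, groups).set_index("group")
        assert df.loc["g1", "external_edges"] == 0
        assert df.loc["g2", "internal_edges"] == 0

    def test_no_lateral_edges(self, t4):
        groups = {"A": "g1", "B": "g1", "C": "g2", "D": "g2"}
        df = group_edge_analysis(_mln(t4, ["1111"]), groups).set_index("group")
        assert (df["internal_freq"] == 0).all()
        assert df["ks_p"].isna().all()

    def test_unassigned_taxon_rejected(self, t4):
        with pytest.raises(ValueError, match="group"):
            group_edge_analysis(_mln(t4, ["1111"]), {"A": "g1"})


class TestKnownBorrowingValidation:
    def test_external_when_taxon_is_an_origin(self, t4):
        sc = {"c0": infer_BORk(t4, row_of(t4, "1010"), BOR1, "c0")}
        table, summary = validate_known_borrowings(t4, sc, [("c0", "C")])
        assert table.loc[0, "classification"] == "external"
        assert summary["detected_pct"] == 100.0

    def test_internal_when_taxon_descends_from_internal_origin(self, t8):
        # presents ABCD + E: origins are the ABCD ancestor and leaf E
        sc = {"c0": infer_BORk(t8, row_of(t8, "11111000"), BOR1, "c0")}
        assert sc["c0"].n_origins == 2
        table, _ = validate_known_borrowings(t8, sc, [("c0", "B")])
        assert table.loc[0, "classification"] == "internal"

    def test_single_origin_not_detected(self, t4):
        sc = {"c0": infer_BORk(t4, row_of(t4, "1100"), BOR1, "c0")}
        _, summary = validate_known_borrowings(t4, sc, [("c0", "A")])
        assert summary["not_detected"] == 1 and summary["detected_pct"] == 0.0

    def test_unknown_ids_rejected(self, t4):
        sc = {"c0": infer_BORk(t4, row_of(t4, "1100"), BOR1, "c0")}
        with pytest.raises(ValueError):
            validate_known_borrowings(t4, sc, [("nope", "A")])
        with pytest.raises(ValueError):
            validate_known_borrowings(t4, sc, [("c0", "nope")])
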