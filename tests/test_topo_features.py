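import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netprio.network_io import GeneSet, InteractionNetwork
from netprio.topo_features import (
    ALL_FEATURES,
    betweenness_all,
    build_feature_matrix,
    clustering_coefficient,
    degree,
    disease_neighbor_count,
    disease_neighbor_ratio,
    mean_shortest_path_to_disease,
)
from oracles import betweenness_brute, clustering_brute, mean_path_to_set_brute

TRIANGLE = InteractionNetwork([("a", "b"), ("b", "c"), ("a", "c")])


class TestDegree:
    def test_triangle(self):
        assert degree(TRIANGLE, "a") == 2

    def test_star(self, star5):
        assert degree(star5, "hub") == 4
        assert degree(star5, "L0") == 1

    def test_isolated(self):
        net = InteractionNetwork(nodes=["x"])
        assert degree(net, "x") == 0

    def test_unknown_gene(self):
        with pytest.raises(KeyError):
            degree(TRIANGLE, "zzz")


class TestDiseaseNeighbors:
    def test_star_center(self, star5):
        d = GeneSet("d", {"L0", "L1"})
        assert disease_neighbor_count(star5, "hub", d) == 2
        assert disease_neighbor_ratio(star5, "hub", d) == pytest.approx(0.5)

    def test_empty_disease(self, star5):
        assert disease_neighbor_count(star5, "hub", GeneSet("d", set())) == 0

    def test_path_middle(self, path3):
        assert disease_neighbor_count(path3, "B", GeneSet("d", {"A", "C"})) == 2

    def test_all_neighbors_disease_ratio_one(self, star5):
        d = GeneSet("d", {f"L{i}" for i in range(4)})
        assert disease_neighbor_ratio(star5, "hub", d) == 1.0

    def test_isolated_ratio_zero(self):
        net = InteractionNetwork(nodes=["x"])
        assert disease_neighbor_ratio(net, "x", GeneSet("d", {"y"})) == 0.0

    def test_exclude_self(self, path3):
        d = GeneSet("d", {"A", "B"})
        # B's neighborhood is {A, C}; self-membership must not matter
        assert disease_neighbor_count(path3, "B", d, exclude_self=True) == 1
        assert disease_neighbor_count(path3, "B", d, exclude_self=False) == 1


class TestBetweenness:
    def test_path3(self, path3):
        b = betweenness_all(path3)
        assert b["B"] == pytest.approx(1.0)
        assert b["A"] == b["C"] == pytest.approx(0.0)

    def test_cycle4_fractional(self):
        # two shortest paths between opposite corners, each interior node
        # carries half a unit for exactly one such pair
        net = InteractionNetwork([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        b = betweenness_all(net)
        assert all(v == pytest.approx(0.5) for v in b.values())

    def test_matches_bruteforce_random(self, request):
        from conftest import random_graph

        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(5, 25))
            nodes, edges = random_graph(rng, n, 0.2)
            net = InteractionNetwork(edges, nodes=nodes)
            expected = betweenness_brute(nodes, edges)
            got = betweenness_all(net)
            for v in nodes:
                assert got[v] == pytest.approx(expected[v], abs=1e-9)


class TestClustering:
    def test_triangle(self):
        assert clustering_coefficient(TRIANGLE, "a") == 1.0

    def test_star_center(self, star5):
        assert clustering_coefficient(star5, "hub") == 0.0

    def test_one_of_three_possible_edges(self):
        net = InteractionNetwork([("g", "a"), ("g", "b"), ("g", "c"), ("a", "b")])
        assert clustering_coefficient(net, "g") == pytest.approx(1 / 3)

    def test_degree_below_two(self, path3):
        assert clustering_coefficient(path3, "A") == 0.0


class TestMeanPathToDisease:
    def test_path_middle(self, path3):
        assert mean_shortest_path_to_disease(path3, "B", GeneSet("d", {"A", "C"})) == 1.0

    def test_adjacent_single_disease(self, path3):
        assert mean_shortest_path_to_disease(path3, "A", GeneSet("d", {"B"})) == 1.0

    def test_unreachable_gives_missing(self):
        net = InteractionNetwork([("a", "b")], nodes=["x"])
        assert math.isnan(mean_shortest_path_to_disease(net, "x", GeneSet("d", {"a"})))

    def test_empty_after_self_exclusion(self, path3):
        with pytest.raises(ValueError):
            mean_shortest_path_to_disease(path3, "A", GeneSet("d", {"A"}))


class TestBuildFeatureMatrix:
    def test_path3_hand_computed_row(self, path3):
        m = build_feature_matrix(path3, ["A", "B", "C"], GeneSet("d", {"A", "C"}))
        row = m.data.loc["B"]
        assert tuple(row[list("DNR")]) == (2.0, 2.0, 1.0)
        assert row["B"] == pytest.approx(1.0)
        assert row["C"] == 0.0
        assert row["M"] == pytest.approx(1.0)

    def test_leave_one_out_m(self, path3):
        m = build_feature_matrix(path3, ["A"], GeneSet("d", {"A", "C"}), leave_one_out=True)
        assert m.data.loc["A", "M"] == pytest.approx(2.0)  # d(A, C)

    def test_no_leave_one_out_includes_self(self, path3):
        m = build_feature_matrix(path3, ["A"], GeneSet("d", {"A", "C"}), leave_one_out=False)
        assert m.data.loc["A", "M"] == pytest.approx(1.0)  # mean of d(A,A)=0, d(A,C)=2

    def test_single_feature_matrix(self, path3):
        m = build_feature_matrix(path3, ["A", "B"], GeneSet("d", {"C"}), features=("D",))
        assert m.feature_names == ("D",)
        assert list(m.data.columns) == ["D"]

    def test_missing_m_imputed_max_plus_one(self):
        net = InteractionNetwork([("a", "b"), ("c", "d")])
        m = build_feature_matrix(net, ["b", "c"], GeneSet("d", {"a"}))
        # c cannot reach the disease gene; M imputed as max finite (1.0) + 1
        assert m.data.loc["b", "M"] == pytest.approx(1.0)
        assert m.data.loc["c", "M"] == pytest.approx(2.0)

    def test_empty_disease_rejected(self, path3):
        with pytest.raises(ValueError):
            build_feature_matrix(path3, ["A"], GeneSet("d", set()))

    def test_m_matches_bruteforce(self, request):
        from conftest import random_graph

        rng = np.random.default_rng(11)
        for _ in range(5):
            nodes, edges = random_graph(rng, 20, 0.15)
            net = InteractionNetwork(edges, nodes=nodes)
            disease = set(rng.choice(nodes, size=4, replace=False))
            m = build_feature_matrix(
                net, nodes, GeneSet("d", disease), features=("M",), impute_missing=False
            )
            for g in nodes:
                expected = mean_path_to_set_brute(nodes, edges, g, disease)
                got = m.data.loc[g, "M"]
                if expected is None:
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(expected, abs=1e-9)

    def test_tsv_serialization_roundtrippable_header(self, path3, tmp_path):
        m = build_feature_matrix(path3, ["A", "B"], GeneSet("d", {"C"}))
        out = tmp_path / "features.tsv"
        with open(out, "w") as fh:
            m.to_tsv(fh)
        text = out.read_text()
        assert text.startswith("#loo=1\t")
        assert "gene\tD\tN\tR\tB\tC\tM" in text


# --- properties --------------------------------------------------------------

edge_strategy = st.lists(
    st.tuples(st.integers(0, 14), st.integers(0, 14)).filter(lambda e: e[0] != e[1]),
    min_size=1,
    max_size=40,
)


@settings(max_examples=40, deadline=None)
@given(edges=edge_strategy, disease_idx=st.sets(st.integers(0, 14), min_size=1, max_size=5))
def test_feature_bounds_properties(edges, disease_idx):
    from hypothesis import assume

    net = InteractionNetwork([(f"g{a}", f"g{b}") for a, b in edges])
    on_network = {f"g{i}" for i in disease_idx} & net.nodes
    assume(len(on_network) >= 2)  # leave-one-out needs a non-degenerate disease set
    disease = GeneSet("d", on_network)
    genes = sorted(net.nodes)
    m = build_feature_matrix(net, genes, disease)
    assert ((m.data["R"] >= 0) & (m.data["R"] <= 1)).all()
    assert ((m.data["C"] >= 0) & (m.data["C"] <= 1)).all()
    assert (m.data["N"] <= m.data["D"]).all()


@settings(max_examples=25, deadline=None)
@given(edges=edge_strategy)
def test_adding_edge_never_decreases_degree(edges):
    net = InteractionNetwork([(f"g{a}", f"g{b}") for a, b in edges])
    genes = sorted(net.nodes)
    if len(genes) < 2:
        return
    a, b = genes[0], genes[-1]
    before = {g: degree(net, g) for g in genes}
    net2 = InteractionNetwork(list(net.edges()) + [(a, b)], nodes=genes)
    for g in genes:
        assert degree(net2, g) >= before[g]


@settings(max_examples=25, deadline=None)
@given(edges=edge_strategy, disease_idx=st.sets(st.integers(0, 14), min_size=2, max_size=6))
def test_removing_disease_gene_never_increases_n(edges, disease_idx):
    net = InteractionNetwork([(f"g{a}", f"g{b}") for a, b in edges])
    disease = {f"g{i}" for i in disease_idx}
    smaller = GeneSet("d", set(list(disease)[1:]))
    for g in sorted(net.nodes):
        n_full = disease_neighbor_count(net, g, GeneSet("d", disease))
        n_small = disease_neighbor_count(net, g, smaller)
        assert n_small <= n_full


def test_disease_equal_to_neighborhood(star5):
    d = GeneSet("d", star5.neighbors("hub"))
    assert disease_neighbor_ratio(star5, "hub", d) == 1.0
    assert mean_shortest_path_to_disease(star5, "hub", d) == 1.0


def test_betweenness_sum_consistency():
    """Sum of betweenness equals sum over pairs of (path length - 1)."""
    from conftest import random_graph

    rng = np.random.default_rng(3)
    nodes, edges = random_graph(rng, 18, 0.2)
    net = InteractionNetwork(edges, nodes=nodes)
    expected = betweenness_brute(nodes, edges)
    assert sum(betweenness_all(net).values()) == pytest.approx(
        sum(expected.values()), abs=1e-9
    )


def test_feature_vector_has_six_components():
    assert ALL_FEATURES == ("D", "N", "R", "B", "C", "M")
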