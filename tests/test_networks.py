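import numpy as np
import pandas as pd
import pytest

from mesopid import networks
from mesopid.exceptions import PathInconsistencyError
from mesopid.networks import InteractionLayer
from oracles import bfs_distances, classify_naive


def layer_from_edges(edges, n_nodes, name="L", k=1):
    return InteractionLayer(
        layer_name=name,
        nodes=tuple(range(n_nodes)),
        edges=frozenset((min(i, j), max(i, j)) for i, j in edges),
        k=k,
    )


def random_layer(n_nodes, p, rng, name):
    edges = {
        (i, j)
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < p
    }
    return layer_from_edges(edges, n_nodes, name)


class TestBuildKnnLayer:
    def weights(self, rows):
        return pd.DataFrame(rows, columns=["i", "j", "z_si"])

    def test_three_nodes_k1_matches_enumeration(self):
        # weights: 0-1 strongest, 0-2 middle, 1-2 weakest
        w = self.weights([(0, 1, 3.0), (0, 2, 2.0), (1, 2, 1.0)])
        layer = networks.build_knn_layer(w, "z_si", k=1)
        # node 0 picks 0-1; node 1 picks 0-1; node 2 picks 0-2
        assert layer.edges == frozenset({(0, 1), (0, 2)})

    def test_complete_graph_at_k_n_minus_1(self, rng):
        rows = [
            (i, j, rng.normal()) for i in range(5) for j in range(i + 1, 5)
        ]
        layer = networks.build_knn_layer(self.weights(rows), "z_si", k=4)
        assert len(layer.edges) == 10

    def test_tie_broken_toward_lower_id(self):
        # node 0 ties between neighbors 1 and 2; nodes 1 and 2 prefer node 3,
        # so only node 0's own tie-break decides whether 0-1 or 0-2 survives
        w = self.weights(
            [(0, 1, 1.0), (0, 2, 1.0), (1, 3, 5.0), (2, 3, 5.0)]
        )
        layer = networks.build_knn_layer(w, "z_si", k=1)
        assert (0, 1) in layer.edges and (0, 2) not in layer.edges

    def test_degenerate_k_warns(self):
        w = self.weights([(0, 1, 1.0)])
        with pytest.warns(UserWarning, match="complete graph"):
            networks.build_knn_layer(w, "z_si", k=5)


class TestCombineLayers:
    def test_union_sizes(self):
        a = layer_from_edges({(0, 1)}, 4, "A")
        b = layer_from_edges({(2, 3)}, 4, "B")
        assert len(networks.combine_layers(a, b).edges) == 2
        assert networks.combine_layers(a, a).edges == a.edges
        c = layer_from_edges({(0, 1), (1, 2)}, 4, "C")
        assert len(networks.combine_layers(a, c).edges) == 2

    def test_node_mismatch_rejected(self):
        a = layer_from_edges(set(), 3, "A")
        b = layer_from_edges(set(), 4, "B")
        with pytest.raises(ValueError):
            networks.combine_layers(a, b)


class TestShortestPaths:
    def test_path_graph(self):
        layer = layer_from_edges({(0, 1), (1, 2)}, 3)
        d = networks.shortest_path_lengths(layer)
        assert d[(0, 2)] == 2

    def test_disconnected_pair_infinite(self):
        layer = layer_from_edges({(0, 1)}, 3)
        assert np.isinf(networks.shortest_path_lengths(layer)[(0, 2)])

    def test_matches_bfs_oracle_on_random_graphs(self, rng):
        for _ in range(50):
            layer = random_layer(12, 0.2, rng, "A")
            got = networks.shortest_path_lengths(layer)
            assert got == bfs_distances(12, set(layer.edges))


class TestClassifyPaths:
    def test_cross_layer_route_is_complementary(self):
        a = layer_from_edges({(1, 2)}, 4, "A")
        b = layer_from_edges({(2, 3)}, 4, "B")
        paths, _ = networks.decompose_multiplex(a, b)
        row = paths[(paths["i"] == 1) & (paths["j"] == 3)].iloc[0]
        assert np.isinf(row.d_a) and np.isinf(row.d_b) and row.d_union == 2
        assert row.category == "complementary"

    def test_edge_in_both_layers_is_shared(self):
        a = layer_from_edges({(0, 1)}, 2, "A")
        paths, _ = networks.decompose_multiplex(a, a)
        assert paths.iloc[0].category == "shared"

    def test_faster_single_layer_is_unique(self):
        du = {(0, 1): 1.0}
        assert networks.classify_paths(
            {(0, 1): 1.0}, {(0, 1): 3.0}, du
        ).iloc[0].category == "unique_a"

    def test_inconsistent_distances_raise(self):
        with pytest.raises(PathInconsistencyError):
            networks.classify_paths({(0, 1): 1.0}, {(0, 1): 2.0}, {(0, 1): 3.0})

    def test_matches_oracle_and_exclusivity_on_random_graphs(self, rng):
        for _ in range(200):
            a = random_layer(15, rng.uniform(0.05, 0.3), rng, "A")
            b = random_layer(15, rng.uniform(0.05, 0.3), rng, "B")
            paths, _ = networks.decompose_multiplex(a, b)
            da = bfs_distances(15, set(a.edges))
            db = bfs_distances(15, set(b.edges))
            dune = bfs_distances(15, set(a.edges | b.edges))
            for row in paths.itertuples():
                key = (row.i, row.j)
                assert row.category == classify_naive(da[key], db[key], dune[key])

    def test_adding_edges_never_lengthens_union_paths(self, rng):
        a = random_layer(12, 0.15, rng, "A")
        b = random_layer(12, 0.15, rng, "B")
        union = networks.combine_layers(a, b)
        base = networks.shortest_path_lengths(union)
        extra = layer_from_edges(set(union.edges) | {(0, 7)}, 12)
        longer = networks.shortest_path_lengths(extra)
        assert all(longer[k] <= base[k] for k in base)


class TestProportions:
    def test_all_shared(self):
        a = layer_from_edges({(0, 1), (1, 2), (0, 2)}, 3, "A")
        _, props = networks.decompose_multiplex(a, a)
        assert (props["shared"] == 1.0).all()

    def test_hand_counted_fixture(self):
        rows = [
            {"i": 0, "j": k, "d_a": 1, "d_b": 1, "d_union": 1, "category": c}
            for k, c in enumerate(
                ["shared", "shared", "unique_a", "complementary"], start=1
            )
        ] + [
            {"i": 1, "j": k, "d_a": 2, "d_b": 2, "d_union": 2, "category": c}
            for k, c in enumerate(["shared", "unique_b"], start=2)
        ]
        props = networks.path_proportions_by_length(pd.DataFrame(rows), long_threshold=2)
        at1 = props[props["path_length"] == 1].iloc[0]
        assert at1["shared"] == pytest.approx(0.5)
        assert at1["unique_a"] == pytest.approx(0.25)
        assert at1["complementary"] == pytest.approx(0.25)
        long_row = props[props["path_length"] == "long"].iloc[0]
        assert long_row["shared"] == pytest.approx(0.5)
        assert long_row["n_pairs"] == 2

    def test_proportions_sum_to_one_per_length(self, rng):
        a = random_layer(15, 0.2, rng, "A")
        b = random_layer(15, 0.2, rng, "B")
        _, props = networks.decompose_multiplex(a, b)
        sums = props[list(networks.CATEGORIES)].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)


class TestAggregate:
    def make_summary(self, value):
        return pd.DataFrame(
            [{"path_length": 1, "n_pairs": 10, "complementary": value,
              "shared": 1 - value, "unique_a": 0.0, "unique_b": 0.0}]
        )

    def test_single_dataset_degenerate_band(self):
        agg = networks.aggregate_over_datasets([self.make_summary(0.3)])
        row = agg.iloc[0]
        assert row["complementary_median"] == row["complementary_lo"] == 0.3

    def test_median_of_three(self):
        agg = networks.aggregate_over_datasets(
            [self.make_summary(v) for v in (0.1, 0.2, 0.9)]
        )
        assert agg.iloc[0]["complementary_median"] == pytest.approx(0.2)

    def test_order_invariance(self):
        forward = networks.aggregate_over_datasets(
            [self.make_summary(v) for v in (0.1, 0.2, 0.9)]
        )
        backward = networks.aggregate_over_datasets(
            [self.make_summary(v) for v in (0.9, 0.2, 0.1)]
        )
        pd.testing.assert_frame_equal(forward, backward)
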