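import numpy as np
import pytest

from grnsage import RunConfig, aggregate_neighbors, embed, topk_pool
from grnsage.autograd import Tensor
from grnsage.embedding import SageLayer
from grnsage.evaluation import _graph_from_records
from grnsage.nn import LSTMCell


def graph_of(n, edges, feats=None, m=4):
    feats = feats if feats is not None else np.zeros((n, m))
    return _graph_from_records(np.asarray(feats, dtype=float), n, edges)


class TestAggregateNeighbors:
    def setup_method(self):
        self.feats = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 2.0]])
        self.graph = graph_of(3, [(0, 1), (0, 2)], self.feats)

    def test_mean_is_arithmetic_mean_of_neighbor_rows(self):
        out = aggregate_neighbors(self.feats, self.graph, "mean")
        np.testing.assert_allclose(out.data[0], [2.0, 1.0])

    def test_max_is_elementwise_max(self):
        out = aggregate_neighbors(self.feats, self.graph, "max")
        np.testing.assert_allclose(out.data[0], [3.0, 2.0])

    def test_empty_neighborhood_aggregates_to_zero(self):
        lonely = graph_of(3, [], self.feats)
        for agg in ("mean", "max"):
            out = aggregate_neighbors(self.feats, lonely, agg)
            np.testing.assert_array_equal(out.data, np.zeros((3, 2)))

    def test_mean_invariant_to_neighbor_insertion_order(self):
        g1 = graph_of(4, [(0, 1), (0, 2), (0, 3)])
        g2 = graph_of(4, [(0, 3), (0, 2), (0, 1)])
        feats = np.random.default_rng(0).standard_normal((4, 3))
        a = aggregate_neighbors(feats, graph_of(4, [(0, 1), (0, 2), (0, 3)], feats), "mean")
        b = aggregate_neighbors(feats, graph_of(4, [(0, 3), (0, 2), (0, 1)], feats), "mean")
        np.testing.assert_allclose(a.data, b.data)

    def test_lstm_reproducible_given_permutation_seed(self):
        rng = np.random.default_rng(1)
        feats = rng.standard_normal((5, 3))
        g = graph_of(5, [(0, 1), (0, 2), (0, 3), (0, 4)], feats)
        lstm = LSTMCell(3, 3, np.random.default_rng(2))
        a = aggregate_neighbors(feats, g, "lstm", lstm=lstm, perm_rng=np.random.default_rng(9))
        b = aggregate_neighbors(feats, g, "lstm", lstm=lstm, perm_rng=np.random.default_rng(9))
        np.testing.assert_array_equal(a.data, b.data)


def brute_force_sage(features, neighbor_sets, W):
    """Independent per-node evaluation of the SAGE update."""
    n, d_in = features.shape
    out = []
    for v in range(n):
        nbrs = sorted(neighbor_sets[v])
        agg = features[nbrs].mean(axis=0) if nbrs else np.zeros(d_in)
        pre = W.T @ np.concatenate([features[v], agg])
        out.append(np.maximum(pre, 0.0))
    return np.stack(out)


class TestSageLayer:
    def test_identity_passthrough_construction(self):
        # W = [I | 0] copies the (non-negative) self features through ReLU
        feats = np.abs(np.random.default_rng(0).standard_normal((4, 3)))
        g = graph_of(4, [(0, 1), (2, 3)], feats)
        layer = SageLayer(3, 3, "mean", np.random.default_rng(1))
        layer.weight.data = np.vstack([np.eye(3), np.zeros((3, 3))])
        out = layer(feats, g)
        np.testing.assert_allclose(out.data, feats)

    def test_relu_clamps_negative_preactivations(self):
        feats = np.ones((2, 2))
        g = graph_of(2, [(0, 1)], feats)
        layer = SageLayer(2, 1, "mean", np.random.default_rng(0))
        layer.weight.data = -np.ones((4, 1))  # pre-activation -4 everywhere
        out = layer(feats, g)
        np.testing.assert_array_equal(out.data, np.zeros((2, 1)))

    def test_matches_per_node_brute_force(self):
        rng = np.random.default_rng(7)
        feats = rng.standard_normal((6, 4))
        edges = [(0, 1), (1, 2), (2, 3), (3, 4), (0, 5)]
        g = graph_of(6, edges, feats)
        layer = SageLayer(4, 3, "mean", rng)
        out = layer(feats, g)
        expected = brute_force_sage(feats, g.neighbor_sets, layer.weight.data)
        np.testing.assert_allclose(out.data, expected, atol=1e-12)


class TestEmbed:
    def test_default_config_shape(self, tiny_setup):
        graph, _ = tiny_setup
        cfg = RunConfig()
        layer = SageLayer(graph.node_features.shape[1], cfg.embed_dim,
                          cfg.aggregator, np.random.default_rng(0))
        X = embed(graph.node_features, graph, [layer])
        assert X.shape == (graph.n_nodes, 256)

    def test_two_hops_reach_two_step_neighbors(self):
        rng = np.random.default_rng(0)
        feats = rng.standard_normal((3, 4))
        layers = [SageLayer(4, 4, "mean", np.random.default_rng(1)),
                  SageLayer(4, 4, "mean", np.random.default_rng(2))]
        g = graph_of(3, [(0, 1), (1, 2)], feats)

        def run(f, n_layers):
            return embed(f, graph_of(3, [(0, 1), (1, 2)], f), layers[:n_layers]).data

        perturbed = feats.copy()
        perturbed[2] += 1.0
        assert not np.allclose(run(feats, 2)[0], run(perturbed, 2)[0])
        np.testing.assert_allclose(run(feats, 1)[0], run(perturbed, 1)[0])

    def test_no_edges_keeps_embeddings_local(self):
        rng = np.random.default_rng(0)
        feats = rng.standard_normal((4, 3))
        layers = [SageLayer(3, 3, "mean", np.random.default_rng(1)),
                  SageLayer(3, 3, "mean", np.random.default_rng(2))]
        base = embed(feats, graph_of(4, [], feats), layers).data
        perturbed = feats.copy()
        perturbed[0] += 2.0
        moved = embed(perturbed, graph_of(4, [], perturbed), layers).data
        np.testing.assert_allclose(base[1:], moved[1:])
        assert not np.allclose(base[0], moved[0])

    def test_empty_layer_list_rejected(self):
        g = graph_of(2, [])
        with pytest.raises(ValueError):
            embed(g.node_features, g, [])


class TestTopkPool:
    def test_worked_example(self):
        X = np.array([[1.0, 0.0], [0.0, 2.0], [3.0, 0.0]])
        p = Tensor(np.array([1.0, 0.0]))
        sel = topk_pool(X, p, 1)
        np.testing.assert_allclose(sel.scores.data, [1.0, 0.0, 3.0])
        assert list(sel.selected_indices) == [2]
        np.testing.assert_allclose(sel.gated_rows.data, [[3 * np.tanh(3.0), 0.0]],
                                   atol=1e-12)
        # independent evaluation of tanh(3)
        assert sel.gated_rows.data[0, 0] == pytest.approx(2.98516, abs=1e-4)

    def test_all_equal_scores_select_lowest_index(self):
        X = np.ones((4, 2))
        sel = topk_pool(X, Tensor(np.array([1.0, 1.0])), 1)
        assert list(sel.selected_indices) == [0]

    def test_k_equals_n_orders_by_score_then_index(self):
        X = np.array([[1.0], [3.0], [1.0], [2.0]])
        sel = topk_pool(X, Tensor(np.array([1.0])), 4)
        assert list(sel.selected_indices) == [1, 3, 0, 2]

    def test_scores_invariant_to_positive_rescaling_of_p(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((6, 4))
        p = rng.standard_normal(4)
        a = topk_pool(X, Tensor(p), 3).scores.data
        b = topk_pool(X, Tensor(17.3 * p), 3).scores.data
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_selection_matches_full_sort_on_random_inputs(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n, d = rng.integers(2, 12), rng.integers(1, 6)
            X = rng.standard_normal((n, d))
            p = rng.standard_normal(d)
            if np.linalg.norm(p) == 0:
                continue
            k = int(rng.integers(1, n + 1))
            sel = topk_pool(X, Tensor(p), k)
            scores = np.maximum(X @ (p / np.linalg.norm(p)), 0.0)
            order = sorted(range(n), key=lambda i: (-scores[i], i))
            assert list(sel.selected_indices) == order[:k]

    def test_invalid_inputs_rejected(self):
        X = np.ones((3, 2))
        with pytest.raises(ValueError):
            topk_pool(X, Tensor(np.array([1.0, 0.0])), 4)
        with pytest.raises(ValueError):
            topk_pool(X, Tensor(np.zeros(2)), 1)

    def test_ungated_rows_are_raw_embeddings(self):
        X = np.array([[1.0, 0.0], [0.0, 2.0], [3.0, 0.0]])
        sel = topk_pool(X, Tensor(np.array([1.0, 0.0])), 1, gate=False)
        np.testing.assert_array_equal(sel.gated_rows.data, [[3.0, 0.0]])

    def test_pruned_adjacency_restricted_to_selection(self):
        feats = np.array([[1.0, 0.0], [0.0, 2.0], [3.0, 0.0]])
        g = graph_of(3, [(0, 2), (1, 2)], feats)
        sel = topk_pool(feats, Tensor(np.array([1.0, 0.0])), 2, graph=g)
        assert list(sel.selected_indices) == [2, 0]
        np.testing.assert_array_equal(sel.pruned_adjacency, [[0.0, 1.0], [1.0, 0.0]])
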