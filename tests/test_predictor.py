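import numpy as np
import pytest

from grnsage import (RunConfig, bce_loss, load_checkpoint, lr_at_epoch, predict_edges,
                     save_checkpoint, score_pairs, train_model)
from grnsage.graph import substream
from grnsage.model import CnnHead, ConfigurationError, GrnModel, bce_with_logits
from grnsage.pairs import assemble_batch

from conftest import small_train_setup


class TestBceLoss:
    def test_uninformative_prediction_gives_ln2(self):
        assert bce_loss([0.5, 0.5], [1.0, 0.0]).item() == pytest.approx(np.log(2), abs=1e-6)

    def test_hand_evaluated_mixed_case(self):
        expected = -(np.log(0.9) + np.log(0.8)) / 2
        assert bce_loss([0.9, 0.2], [1.0, 0.0]).item() == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(0.164252, abs=1e-6)

    def test_perfect_prediction_limit(self):
        loss = bce_loss([1.0, 0.0], [1.0, 0.0]).item()
        assert 0.0 <= loss < 1e-6

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss([0.5], [1.0, 0.0])

    def test_logit_form_matches_probability_form(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(20) * 3
        y = (rng.uniform(size=20) < 0.5).astype(float)
        from grnsage.autograd import Tensor

        a = bce_with_logits(Tensor(z), y).item()
        b = bce_loss(1 / (1 + np.exp(-z)), y).item()
        assert a == pytest.approx(b, rel=1e-9)


class TestLrSchedule:
    @pytest.mark.parametrize("epoch,expected", [(0, 0.01), (9, 0.01), (10, 0.008),
                                                (19, 0.008), (20, 0.0064), (25, 0.0064)])
    def test_step_decay_values(self, epoch, expected):
        assert lr_at_epoch(epoch, 0.01, 0.8, 10) == pytest.approx(expected, rel=1e-12)

    def test_closed_form_for_arbitrary_epoch(self):
        for epoch in range(50):
            assert lr_at_epoch(epoch, 0.05, 0.5, 7) == 0.05 * 0.5 ** (epoch // 7)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            lr_at_epoch(5, 0.01, 0.8, 0)
        with pytest.raises(ValueError):
            lr_at_epoch(-1, 0.01, 0.8, 10)


def tiny_model(graph, seed=3, **overrides):
    cfg = RunConfig(embed_dim=8, epochs=0, seed=seed, **overrides)
    model = GrnModel(graph.node_features.shape[1], cfg, substream(seed, "model_init"))
    model.eval()
    return model, cfg


class TestScorePairs:
    def test_outputs_are_probabilities(self, tiny_setup):
        graph, _ = tiny_setup
        model, _ = tiny_model(graph)
        probs = model.forward(graph, np.array([(0, 1), (2, 4), (5, 0)], dtype=np.intp)).data
        assert np.all((probs >= 0) & (probs <= 1))

    def test_zeroed_head_scores_exactly_half(self, tiny_setup):
        graph, _ = tiny_setup
        model, _ = tiny_model(graph)
        model.forward(graph, np.array([(0, 1)], dtype=np.intp))  # materialize
        for layer in (model.head.fc1.inner, model.head.fc2.inner):
            layer.weight.data[:] = 0.0
            layer.bias.data[:] = 0.0
        probs = model.forward(graph, np.array([(0, 1), (3, 2)], dtype=np.intp)).data
        np.testing.assert_array_equal(probs, [0.5, 0.5])

    def test_duplicated_inputs_score_identically_in_eval_mode(self, tiny_setup):
        graph, _ = tiny_setup
        model, _ = tiny_model(graph)
        from grnsage.autograd import Tensor
        from grnsage.embedding import embed, topk_pool

        X = embed(Tensor(graph.node_features), graph, model.sage_layers)
        pool = topk_pool(X, model.pool_p, 1, graph)
        batch = assemble_batch(X, pool, [(0, 1), (0, 1), (0, 1)])
        probs = score_pairs(batch, model.head)
        assert probs[0] == probs[1] == probs[2]

    def test_mismatched_shapes_rejected(self, tiny_setup):
        graph, _ = tiny_setup
        model, _ = tiny_model(graph)
        from grnsage.pairs import PairFeatureMatrix

        bad = [PairFeatureMatrix(np.zeros((3, 8)), 0, 1),
               PairFeatureMatrix(np.zeros((2, 8)), 0, 1)]
        with pytest.raises(ValueError):
            score_pairs(bad, model.head)


class TestCnnHeadGeometry:
    def test_too_few_rows_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            CnnHead(rows=1, width=16, n_layers=3, kernel_size=2,
                    rng=np.random.default_rng(0))

    def test_three_blocks_handle_collapsed_row_extent(self):
        # rows=3 collapses to one row after the first block; deeper kernels clip
        head = CnnHead(rows=3, width=16, n_layers=3, kernel_size=2,
                       rng=np.random.default_rng(0))
        from grnsage.autograd import Tensor

        out = head(Tensor(np.random.default_rng(1).standard_normal((4, 1, 3, 16))))
        assert out.shape == (4,)


class TestTrainModel:
    def test_same_seed_gives_identical_loss_traces(self, tiny_setup):
        _, mixed, graph = small_train_setup(seed=2)
        cfg = RunConfig(embed_dim=16, epochs=3, batch_size=16, seed=5)
        t1 = train_model(mixed, graph, cfg).loss_trace
        t2 = train_model(mixed, graph, cfg).loss_trace
        assert t1 == t2

    def test_training_reduces_loss_on_planted_network(self, fixture_data, fixture_labels,
                                                      fixture_run_config):
        from grnsage import sample_negatives
        from grnsage.evaluation import _graph_from_records
        from grnsage.graph import prepare_node_features

        expr, _ = fixture_data
        mixed = sample_negatives(fixture_labels, 1.0, 1)
        graph = _graph_from_records(prepare_node_features(expr), expr.n_genes,
                                    mixed.positives)
        cfg = fixture_run_config.with_overrides(embed_dim=64, epochs=15)
        state = train_model(mixed, graph, cfg)
        assert state.loss_trace[-1] < state.loss_trace[0]

    def test_zero_epochs_returns_initialized_state(self, tiny_setup):
        _, mixed, graph = small_train_setup(seed=3)
        cfg = RunConfig(embed_dim=16, epochs=0, seed=1)
        state = train_model(mixed, graph, cfg)
        assert state.epoch == 0
        assert state.loss_trace == []
        preds = predict_edges(state, graph, [(0, 10)])
        assert 0.0 <= preds[0][2] <= 1.0

    def test_single_class_training_set_rejected(self, tiny_setup):
        from grnsage.graph import LabeledEdgeSet

        graph, _ = tiny_setup
        pos_only = LabeledEdgeSet([(0, 1, 1), (1, 2, 1)], tf_pool={0, 1}, target_pool={1, 2})
        with pytest.raises(ValueError, match="both"):
            train_model(pos_only, graph, RunConfig(embed_dim=8, epochs=1, seed=0))

    def test_lr_trace_follows_schedule(self):
        _, mixed, graph = small_train_setup(seed=4)
        cfg = RunConfig(embed_dim=16, epochs=12, batch_size=64, seed=2,
                        lr_interval_epochs=5)
        state = train_model(mixed, graph, cfg)
        assert state.lr == pytest.approx(lr_at_epoch(11, cfg.lr0, cfg.lr_decay, 5))


class TestPredictEdges:
    def test_scores_in_unit_interval_and_repeatable(self):
        _, mixed, graph = small_train_setup(seed=5)
        cfg = RunConfig(embed_dim=16, epochs=4, batch_size=16, seed=7)
        state = train_model(mixed, graph, cfg)
        pairs = [(i, j) for i, j, _ in mixed.records]
        a = predict_edges(state, graph, pairs)
        b = predict_edges(state, graph, pairs)
        assert a == b
        assert all(0.0 <= p <= 1.0 for _, _, p in a)

    def test_out_of_range_index_rejected(self):
        _, mixed, graph = small_train_setup(seed=5)
        state = train_model(mixed, graph, RunConfig(embed_dim=8, epochs=0, seed=0))
        with pytest.raises(IndexError):
            predict_edges(state, graph, [(0, 10_000)])

    def test_recovers_planted_signal_above_chance(self, fixture_data, fixture_labels):
        """Held-out AUROC beats 0.5 by > 3x the across-seed standard error."""
        from grnsage import sample_negatives
        from grnsage.evaluation import _graph_from_records, auroc
        from grnsage.graph import make_folds, prepare_node_features

        expr, _ = fixture_data
        mixed = sample_negatives(fixture_labels, 1.0, 1)  # fixed data across seeds
        features = prepare_node_features(expr)
        aurocs = []
        for seed in range(1, 11):
            cfg = RunConfig(embed_dim=32, epochs=15, batch_size=16, seed=seed)
            split = make_folds(mixed, 5, seed)
            train = mixed.subset(split.train_indices(0))
            test = mixed.subset(split.test_indices(0))
            graph = _graph_from_records(features, expr.n_genes, train.positives)
            state = train_model(train, graph, cfg)
            preds = predict_edges(state, graph, [(i, j) for i, j, _ in test.records])
            aurocs.append(auroc([p for _, _, p in preds],
                                [y for _, _, y in test.records]))
        mean = np.mean(aurocs)
        se = np.std(aurocs, ddof=1) / np.sqrt(len(aurocs))
        assert mean - 0.5 > 3 * se


class TestCheckpoint:
    def test_round_trip_is_bit_exact(self, tmp_path):
        _, mixed, graph = small_train_setup(seed=6)
        cfg = RunConfig(embed_dim=16, epochs=2, batch_size=32, seed=3)
        state = train_model(mixed, graph, cfg)
        state.gene_ids = [f"g{i}" for i in range(graph.n_nodes)]
        path = tmp_path / "model.npz"
        save_checkpoint(state, path)
        loaded = load_checkpoint(path)
        assert loaded.config == state.config
        assert loaded.loss_trace == state.loss_trace
        assert loaded.gene_ids == state.gene_ids
        for key, value in state.model.named_state().items():
            np.testing.assert_array_equal(loaded.model.named_state()[key], value)
        pairs = [(i, j) for i, j, _ in mixed.records[:10]]
        assert predict_edges(loaded, graph, pairs) == predict_edges(state, graph, pairs)
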