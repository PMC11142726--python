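import numpy as np
import pytest

from grnsage import RunConfig, build_labeled_edges, make_fixture
from grnsage.evaluation import _graph_from_records
from grnsage.graph import prepare_node_features


@pytest.fixture(scope="session")
def fixture_data():
    """Canonical planted benchmark: 100 genes, 10 TFs, 200 cells."""
    expr, edges = make_fixture()
    return expr, edges


@pytest.fixture(scope="session")
def fixture_labels(fixture_data):
    expr, edges = fixture_data
    return build_labeled_edges(expr, edges)


@pytest.fixture(scope="session")
def fixture_run_config():
    """Desk-scale training configuration used for fixture runs throughout."""
    return RunConfig(epochs=40, batch_size=16, seed=1)


@pytest.fixture()
def tiny_setup():
    """A 6-node path graph with random positive features, for model-level tests."""
    rng = np.random.default_rng(0)
    n, m = 6, 5
    feats = np.abs(rng.standard_normal((n, m))) + 0.1
    pairs = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)]
    graph = _graph_from_records(feats, n, pairs)
    return graph, pairs


def small_train_setup(seed=1, n_genes=40, n_tfs=5, n_cells=60, noise_sd=0.5):
    """Small planted problem + mixed labels + training graph, for predictor tests."""
    from grnsage import sample_negatives

    expr, edges = make_fixture(preset=dict(n_genes=n_genes, n_tfs=n_tfs,
                                           n_cells=n_cells, noise_sd=noise_sd,
                                           mean_out_degree=4.0, seed=seed))
    labels = build_labeled_edges(expr, edges)
    mixed = sample_negatives(labels, 1.0, seed)
    feats = prepare_node_features(expr)
    graph = _graph_from_records(feats, expr.n_genes, mixed.positives)
    return expr, mixed, graph
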