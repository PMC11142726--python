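"""Train on 20% of reference edges, score the rest, and categorize predictions.

This mirrors the workflow used to reconstruct a network for a new dataset:
a small labeled subset (20% of known edges plus matched negatives) trains
the model, every remaining TF x target pair is scored, and each evaluated
edge is categorized: red = known edge recovered, green = known edge
missed, blue = non-edge correctly rejected, extra = non-edge predicted.
"""

import numpy as np

from grnsage import (RunConfig, auprc, auroc, build_labeled_edges, categorize_edges,
                     make_fixture, predict_edges, sample_negatives, train_model)
from grnsage.evaluation import graph_from_records
from grnsage.graph import prepare_node_features, substream

# denser planted benchmark than the CV fixture: a 20% training split needs
# enough reference edges (~400 here) to be informative
expr, edges = make_fixture(preset=dict(n_genes=100, n_tfs=20, mean_out_degree=25.0,
                                       n_cells=400, noise_sd=0.5, seed=1))
labels = build_labeled_edges(expr, edges)
config = RunConfig(epochs=40, batch_size=16, seed=1)

n_train = int(round(0.2 * len(labels.records)))
rng = substream(config.seed, "split")
chosen = sorted(int(c) for c in rng.choice(len(labels.records), n_train, replace=False))
train_pos = labels.subset(chosen)
mixed = sample_negatives(train_pos, config.neg_ratio, config.seed)
print(f"training on {n_train} positives + {len(mixed.records) - n_train} negatives "
      f"out of {len(labels.records)} reference edges")

graph = graph_from_records(prepare_node_features(expr), expr.n_genes, mixed.positives)
state = train_model(mixed, graph, config)
print(f"loss: {state.loss_trace[0]:.3f} (first epoch) -> {state.loss_trace[-1]:.3f} (last)")

train_pairs = {(i, j) for i, j, _ in mixed.records}
candidates = sorted((i, j) for i in labels.tf_pool for j in labels.target_pool
                    if i != j and (i, j) not in train_pairs)
preds = predict_edges(state, graph, candidates)
scores = np.array([p for _, _, p in preds])
truth = np.array([1 if (i, j) in labels.reference_pairs else 0 for i, j, _ in preds])

print(f"scored {len(preds)} held-out TF x target pairs: "
      f"AUROC {auroc(scores, truth):.3f}, AUPRC {auprc(scores, truth):.3f}")
cats = categorize_edges(scores, truth, config.threshold)
counts = {c: cats.count(c) for c in ("red", "green", "blue", "extra")}
print(f"edge categories: {counts}")
print(f"evaluated sparsity (true-edge fraction): {truth.mean():.3f}")
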