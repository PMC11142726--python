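"""Embed genes with a SAGE layer, pool the most influential nodes, build a pair matrix.

Each gene node starts from its prepared expression row (log1p +
standardization), one aggregation hop mixes neighbor information through a
learned linear map, and Top-k pooling scores every node by projection onto
a learnable direction p.  The pair matrix for a candidate edge (i, j)
stacks [h_i; h_j; pooled rows] — the object the CNN head classifies.
"""

import numpy as np

from grnsage import (assemble_pair_matrix, build_gene_graph, build_labeled_edges,
                     embed, make_fixture, topk_pool)
from grnsage.embedding import SageLayer
from grnsage.nn import Parameter

expr, edges = make_fixture()
graph = build_gene_graph(expr, edges)

rng = np.random.default_rng(0)
layer = SageLayer(in_dim=expr.n_cells, out_dim=64, aggregator="mean", rng=rng)
X = embed(graph.node_features, graph, [layer])
print(f"embedding matrix: {X.shape[0]} genes x {X.shape[1]} dims, "
      f"all entries >= 0 after ReLU: {bool((X.data >= 0).all())}")

p = Parameter(rng.standard_normal(64))
sel = topk_pool(X, p, k=1, graph=graph)
top = int(sel.selected_indices[0])
print(f"top-1 influential node: {expr.gene_ids[top]} "
      f"(score {sel.scores.data[top]:.3f}); scores are ReLU(X p / ||p||)")

labels = build_labeled_edges(expr, edges)
i, j, _ = labels.records[0]
pair = assemble_pair_matrix(X, sel, i, j)
print(f"pair matrix for {expr.gene_ids[i]} -> {expr.gene_ids[j]}: "
      f"shape {pair.rows.shape} = (k+2) x d with k=1")
print("Row 0 is the regulator embedding, row 1 the target, row 2 the gated")
print("top node - a global context row shared by every candidate edge.")
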