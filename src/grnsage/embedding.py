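"""GraphSAGE-style node embedding and Top-k pooling.

A SAGE layer updates every gene node as

    h_v <- ReLU( W . concat(h_v, AGG({h_u : u in N(v)})) )

where AGG is the mean (default), elementwise max, or the final hidden state
of an LSTM run over a seeded random permutation of the neighbors.  Nodes
with empty neighborhoods aggregate to the zero vector.  One layer is
applied per hop, so ``hops`` layers give each embedding a receptive field
of exactly the ``hops``-ball around the node.  No row normalization is
applied to the embeddings.

Top-k pooling scores every node by the ReLU of its projection onto a
learnable direction p (normalized by ||p||), selects the k highest-scoring
nodes (ties broken by lowest node index), and gates the selected rows by
tanh of their scores so the selection stays differentiable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, concat, segment_max
from .graph import GeneGraph
from .nn import LSTMCell, Module, Parameter, _glorot, stack_rows

__all__ = ["SageLayer", "PoolingSelection", "aggregate_neighbors", "embed", "topk_pool"]


def _mean_adjacency(graph: GeneGraph) -> np.ndarray:
    """Row-normalized adjacency: row v averages over N(v); empty rows stay zero."""
    n = graph.n_nodes
    a = np.zeros((n, n))
    for v, nbrs in enumerate(graph.neighbor_sets):
        if nbrs:
            a[v, sorted(nbrs)] = 1.0 / len(nbrs)
    return a


def aggregate_neighbors(features, graph: GeneGraph, aggregator: str = "mean",
                        lstm: LSTMCell | None = None,
                        perm_rng: np.random.Generator | None = None) -> Tensor:
    """Aggregate neighbor feature rows per node; empty N(v) yields zeros."""
    h = features if isinstance(features, Tensor) else Tensor(features)
    if aggregator == "mean":
        return Tensor(_mean_adjacency(graph)) @ h
    if aggregator == "max":
        return segment_max(h, [sorted(nbrs) for nbrs in graph.neighbor_sets])
    if aggregator == "lstm":
        if lstm is None:
            raise ValueError("lstm aggregator requires an LSTMCell")
        if perm_rng is None:
            raise ValueError("lstm aggregator requires a neighbor-permutation rng")
        d = h.shape[1]
        rows = []
        for nbrs in graph.neighbor_sets:
            if not nbrs:
                rows.append(Tensor(np.zeros(d)))
                continue
            idx = np.array(sorted(nbrs))
            idx = idx[perm_rng.permutation(len(idx))]
            rows.append(lstm.run_sequence(h[idx]))
        return stack_rows(rows)
    raise ValueError(f"unknown aggregator {aggregator!r}")


class SageLayer(Module):
    """One aggregation hop: h_v <- ReLU(W . concat(h_v, h_N(v)))."""

    def __init__(self, in_dim: int, out_dim: int, aggregator: str,
                 rng: np.random.Generator):
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        self.aggregator = aggregator
        self.weight = Parameter(_glorot(rng, 2 * in_dim, out_dim, (2 * in_dim, out_dim)))
        self.lstm = LSTMCell(in_dim, in_dim, rng) if aggregator == "lstm" else None

    def __call__(self, features, graph: GeneGraph,
                 perm_rng: np.random.Generator | None = None) -> Tensor:
        h = features if isinstance(features, Tensor) else Tensor(features)
        if h.shape[1] != self.in_dim:
            raise ValueError(f"expected {self.in_dim} input features, got {h.shape[1]}")
        agg = aggregate_neighbors(h, graph, self.aggregator, lstm=self.lstm,
                                  perm_rng=perm_rng)
        return (concat([h, agg], axis=1) @ self.weight).relu()


def embed(features, graph: GeneGraph, layers: list[SageLayer],
          perm_rng: np.random.Generator | None = None) -> Tensor:
    """Sequentially apply one SAGE layer per hop; returns the n x d embedding matrix."""
    if not layers:
        raise ValueError("embed requires at least one SAGE layer")
    h = features if isinstance(features, Tensor) else Tensor(features)
    for layer in layers:
        h = layer(h, graph, perm_rng=perm_rng)
    return h


@dataclass
class PoolingSelection:
    """Result of Top-k pooling over the embedding matrix."""

    scores: Tensor               # n-vector of ReLU-projected magnitudes
    selected_indices: np.ndarray  # k indices, by descending score then lowest index
    gated_rows: Tensor           # k x d: X[idx] gated by tanh(score) (or raw rows)
    pruned_adjacency: np.ndarray  # k x k adjacency restricted to the selection

    @property
    def k(self) -> int:
        return len(self.selected_indices)


def topk_pool(X, p: Tensor, k: int, graph: GeneGraph | None = None,
              gate: bool = True) -> PoolingSelection:
    """Select the k most globally influential nodes from the embedding matrix.

    scores = ReLU(X p / ||p||); the k largest scores win, ties broken by
    lowest node index.  Selected rows are gated elementwise by tanh(score),
    keeping the selection differentiable; ``gate=False`` returns the raw
    rows instead.  The adjacency restricted to the selection is also
    returned (for completeness; downstream pair assembly uses only the
    selected rows).
    """
    x = X if isinstance(X, Tensor) else Tensor(X)
    p = p if isinstance(p, Tensor) else Tensor(p)
    n = x.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    norm = float(np.linalg.norm(p.data))
    if norm == 0.0:
        raise ValueError("projection vector p must be nonzero")
    scores = (x @ (p / (p * p).sum().sqrt())).relu()
    # descending score, ties by lowest index
    idx = np.lexsort((np.arange(n), -scores.data))[:k]
    selected = x[idx]
    if gate:
        selected = selected * scores[idx].reshape(-1, 1).tanh()
    if graph is not None:
        a = np.zeros((n, n))
        for v, nbrs in enumerate(graph.neighbor_sets):
            if nbrs:
                a[v, sorted(nbrs)] = 1.0
        pruned = a[np.ix_(idx, idx)]
    else:
        pruned = np.zeros((k, k))
    return PoolingSelection(scores=scores, selected_indices=idx,
                            gated_rows=selected, pruned_adjacency=pruned)
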