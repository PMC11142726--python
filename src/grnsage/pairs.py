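"""Per-edge feature-matrix assembly.

Each candidate directed edge (i, j) is represented by a (k+2) x d matrix:
row 0 is the embedding of the putative regulator i, row 1 the embedding of
the putative target j, and rows 2..k+1 the (gated) rows of the k pooled
globally influential nodes, in descending score order.  Direction is
encoded purely by row order, so the matrix for (i, j) differs from that
for (j, i) whenever the two embeddings differ.  With pooling disabled
(k = 0) the matrix is just the 2 x d stack of the two endpoint embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, concat
from .embedding import PoolingSelection

__all__ = ["PairFeatureMatrix", "assemble_pair_matrix", "assemble_batch", "assemble_batch_tensor"]


@dataclass
class PairFeatureMatrix:
    rows: np.ndarray  # (k+2) x d
    tf_index: int
    target_index: int

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=np.float64)
        if self.rows.ndim != 2 or self.rows.shape[0] < 2:
            raise ValueError("pair feature matrix must have at least the two endpoint rows")


def _check_index(idx: int, n: int) -> None:
    if not (0 <= idx < n):
        raise IndexError(f"node index {idx} out of range for {n} nodes")


def assemble_pair_matrix(X, pool: PoolingSelection | None, i: int, j: int) -> PairFeatureMatrix:
    """Stack [h_i; h_j; pooled rows] for one candidate edge i -> j."""
    x = X.data if isinstance(X, Tensor) else np.asarray(X, dtype=np.float64)
    _check_index(i, x.shape[0])
    _check_index(j, x.shape[0])
    parts = [x[i], x[j]]
    if pool is not None and pool.k > 0:
        pooled = pool.gated_rows.data if isinstance(pool.gated_rows, Tensor) else pool.gated_rows
        parts.extend(pooled)
    return PairFeatureMatrix(rows=np.stack(parts), tf_index=i, target_index=j)


def assemble_batch(X, pool: PoolingSelection | None, pairs) -> list[PairFeatureMatrix]:
    """Order-preserving batch assembly; pooled rows are shared across the batch."""
    if len(pairs) == 0:
        raise ValueError("assemble_batch requires at least one pair")
    return [assemble_pair_matrix(X, pool, i, j) for i, j in pairs]


def assemble_batch_tensor(X: Tensor, pool: PoolingSelection | None, pairs) -> Tensor:
    """Differentiable batch assembly -> (B, 1, k+2, d) tensor for the CNN head."""
    if len(pairs) == 0:
        raise ValueError("assemble_batch_tensor requires at least one pair")
    n, d = X.shape
    pairs = np.asarray(pairs, dtype=np.intp)
    for i, j in pairs:
        _check_index(int(i), n)
        _check_index(int(j), n)
    B = pairs.shape[0]
    endpoints = X[pairs.reshape(-1)].reshape(B, 2, d)
    if pool is not None and pool.k > 0:
        k = pool.k
        pooled = pool.gated_rows.reshape(1, k, d).broadcast_to((B, k, d))
        stacked = concat([endpoints, pooled], axis=1)
    else:
        stacked = endpoints
    rows = stacked.shape[1]
    return stacked.reshape(B, 1, rows, d)
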