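"""Gene graph construction and labeled-edge management.

The aggregation graph is, by default, the undirected (symmetrized) view of
the training-positive edges: regulators see their targets and vice versa,
which is the common convention for SAGE-style neighborhood aggregation on
directed biological graphs.  A directed alternative is available via
``directed_neighbors``.

Leakage discipline: per-fold aggregation graphs are built from training
positives only, so no test-fold regulatory edge ever contributes to the
embeddings used to score it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import EdgeList, ExpressionMatrix

__all__ = [
    "GeneGraph",
    "LabeledEdgeSet",
    "FoldSplit",
    "substream",
    "prepare_node_features",
    "build_gene_graph",
    "build_labeled_edges",
    "sample_negatives",
    "make_folds",
]

# fixed purpose keys so every random stream is derived, not shared
_PURPOSES = {"negatives": 1, "folds": 2, "model_init": 3, "shuffle": 4,
             "lstm_perm": 5, "grn": 6, "expression": 7, "split": 8, "permute": 9}


def substream(seed: int, purpose: str, index: int = 0) -> np.random.Generator:
    """Named, reproducible random substream derived from the run seed."""
    key = _PURPOSES[purpose]
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key, int(index)))
    return np.random.default_rng(ss)


@dataclass
class GeneGraph:
    """Node neighborhoods used for aggregation plus prepared node features."""

    n_nodes: int
    neighbor_sets: list[set[int]]
    node_features: np.ndarray  # n x m prepared expression rows

    def __post_init__(self):
        for v, nbrs in enumerate(self.neighbor_sets):
            if v in nbrs:
                raise ValueError(f"node {v} appears in its own neighbor set")
            for u in nbrs:
                if not (0 <= u < self.n_nodes):
                    raise ValueError(f"neighbor index {u} out of range for {self.n_nodes} nodes")


@dataclass
class LabeledEdgeSet:
    """Directed (tf_index, target_index, label) records with the TF/target role pools."""

    records: list[tuple[int, int, int]]
    tf_pool: set[int]
    target_pool: set[int]
    reference_pairs: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self):
        pairs = [(i, j) for i, j, _ in self.records]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (tf, target) pair across labeled records")

    @property
    def positives(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j, y in self.records if y == 1]

    @property
    def negatives(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j, y in self.records if y == 0]

    def subset(self, indices) -> "LabeledEdgeSet":
        return LabeledEdgeSet(
            [self.records[i] for i in indices],
            tf_pool=self.tf_pool,
            target_pool=self.target_pool,
            reference_pairs=self.reference_pairs,
        )


@dataclass
class FoldSplit:
    fold_assignments: np.ndarray  # record index -> fold id
    n_folds: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments != fold)


def prepare_node_features(expr: ExpressionMatrix, log_transform: bool = True,
                          standardize: bool = True) -> np.ndarray:
    """Prepare expression rows as node features.

    ``log_transform`` applies x -> log(1+x); ``standardize`` centers each
    gene row to mean 0, population variance 1 (constant rows become zeros).
    """
    x = np.array(expr.values, dtype=np.float64)
    if log_transform:
        x = np.log1p(x)
    if standardize:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        x = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return x


def build_gene_graph(expr: ExpressionMatrix, train_positive_edges: EdgeList,
                     log_transform: bool = True, standardize: bool = True,
                     directed_neighbors: bool = False) -> GeneGraph:
    """Build the aggregation graph over all genes from training positives only."""
    index = expr.gene_index()
    n = expr.n_genes
    neighbor_sets: list[set[int]] = [set() for _ in range(n)]
    for a, b in train_positive_edges:
        if a not in index:
            raise KeyError(f"edge endpoint {a!r} not present in the expression matrix")
        if b not in index:
            raise KeyError(f"edge endpoint {b!r} not present in the expression matrix")
        i, j = index[a], index[b]
        if i == j:
            continue
        neighbor_sets[i].add(j)
        if not directed_neighbors:
            neighbor_sets[j].add(i)
    features = prepare_node_features(expr, log_transform=log_transform, standardize=standardize)
    return GeneGraph(n_nodes=n, neighbor_sets=neighbor_sets, node_features=features)


def build_labeled_edges(expr: ExpressionMatrix, reference: EdgeList) -> LabeledEdgeSet:
    """Positive records from the reference network, with TF/target role pools."""
    index = expr.gene_index()
    records = []
    tf_pool: set[int] = set()
    target_pool: set[int] = set()
    for a, b in reference:
        if a not in index:
            raise KeyError(f"reference TF {a!r} not present in the expression matrix")
        if b not in index:
            raise KeyError(f"reference target {b!r} not present in the expression matrix")
        i, j = index[a], index[b]
        records.append((i, j, 1))
        tf_pool.add(i)
        target_pool.add(j)
    return LabeledEdgeSet(records, tf_pool=tf_pool, target_pool=target_pool,
                          reference_pairs={(i, j) for i, j, _ in records})


def sample_negatives(positives: LabeledEdgeSet, neg_ratio: float, seed: int) -> LabeledEdgeSet:
    """Uniformly sample non-edges from tf_pool x target_pool as label-0 records.

    Candidates exclude every reference-network pair (not just the positives
    handed in) and self-pairs; the draw is without replacement and
    deterministic given ``seed``.
    """
    forbidden = set(positives.reference_pairs) | {(i, j) for i, j, _ in positives.records}
    candidates = sorted(
        (i, j)
        for i in positives.tf_pool
        for j in positives.target_pool
        if i != j and (i, j) not in forbidden
    )
    n_pos = sum(1 for _, _, y in positives.records if y == 1)
    n_requested = int(np.ceil(neg_ratio * n_pos))
    if n_requested > len(candidates):
        raise ValueError(
            f"negative sampling needs {n_requested} candidate pairs but only "
            f"{len(candidates)} are available"
        )
    rng = substream(seed, "negatives")
    chosen = rng.choice(len(candidates), size=n_requested, replace=False)
    negatives = [candidates[int(c)] for c in chosen]
    records = list(positives.records) + [(i, j, 0) for i, j in negatives]
    return LabeledEdgeSet(records, tf_pool=positives.tf_pool,
                          target_pool=positives.target_pool,
                          reference_pairs=positives.reference_pairs)


def make_folds(labels: LabeledEdgeSet, n_folds: int, seed: int) -> FoldSplit:
    """Shuffle records by seed, deal round-robin; fold sizes differ by at most 1."""
    n = len(labels.records)
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    if n_folds > n:
        raise ValueError(f"cannot split {n} records into {n_folds} folds")
    rng = substream(seed, "folds")
    order = rng.permutation(n)
    assignments = np.empty(n, dtype=np.int64)
    for rank, rec in enumerate(order):
        assignments[rec] = rank % n_folds
    return FoldSplit(fold_assignments=assignments, n_folds=n_folds)
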