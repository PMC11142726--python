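"""Metrics and the k-fold cross-validation protocol.

AUROC is computed as the tie-aware Mann-Whitney statistic (probability a
random positive outranks a random negative, ties counted half), AUPRC as
the step-wise sum of precision x recall-increment over descending score
thresholds.  Confusion-based rates follow the usual definitions, with
zero denominators reported as 0 alongside a logged warning.

Cross-validation mirrors the supervised GRN protocol: negatives are
sampled once from the TF x target role pools, mixed with the reference
positives, shuffled into equal folds, and each fold is scored by a model
trained on the remaining folds with an aggregation graph built from the
training positives only (no test edge can leak into the embeddings).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .graph import (GeneGraph, LabeledEdgeSet, make_folds, prepare_node_features,
                    sample_negatives, substream)
from .io import ExpressionMatrix, RunConfig
from .model import TrainState, predict_edges, train_model

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "rates",
    "auroc",
    "auprc",
    "cross_validate",
    "categorize_edges",
    "graph_from_records",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Count TP/FP/TN/FN with 'predicted positive' meaning score >= threshold."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _safe_ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reporting 0", name)
        return 0.0
    return num / den


def rates(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(FPR, TPR, Precision, Recall); TPR and Recall are the same quantity."""
    fpr = _safe_ratio(c.fp, c.fp + c.tn, "FPR")
    tpr = _safe_ratio(c.tp, c.tp + c.fn, "TPR")
    precision = _safe_ratio(c.tp, c.tp + c.fp, "Precision")
    recall = _safe_ratio(c.tp, c.tp + c.fn, "Recall")
    return fpr, tpr, precision, recall


def auroc(scores, labels) -> float:
    """Tie-aware rank AUROC: P(score+ > score-) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes to be present")
    ranks = rankdata(scores)
    rank_sum = float(ranks[labels == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve by step-wise summation.

    Thresholds sweep the descending unique scores; each recall increment
    contributes its increment times the precision at that threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    if n_pos == 0:
        raise ValueError("AUPRC requires at least one positive")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order] == 1
    tp_cum = np.cumsum(sorted_labels)
    pred_cum = np.arange(1, len(scores) + 1)
    # threshold boundaries: last position of each unique score
    boundary = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tp = tp_cum[boundary]
    pp = pred_cum[boundary]
    precision = tp / pp
    recall = tp / n_pos
    recall_prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - recall_prev) * precision))


def categorize_edges(scores, labels, threshold: float = 0.5) -> list[str]:
    """Classify each evaluated edge.

    red = ground-truth edge predicted positive (TP); green = ground-truth
    edge predicted negative (FN); blue = non-edge predicted negative (TN);
    false positives carry no conventional color and are emitted as "extra".
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    out = []
    for s, y in zip(scores, labels):
        pred = s >= threshold
        if y == 1:
            out.append("red" if pred else "green")
        else:
            out.append("extra" if pred else "blue")
    return out


@dataclass
class FoldMetrics:
    fold: int
    counts: ConfusionCounts
    fpr: float
    tpr: float
    precision: float
    recall: float
    auroc: float
    auprc: float

    def as_row(self) -> dict:
        return {
            "fold": self.fold, "tp": self.counts.tp, "fp": self.counts.fp,
            "tn": self.counts.tn, "fn": self.counts.fn, "fpr": self.fpr,
            "tpr": self.tpr, "precision": self.precision, "recall": self.recall,
            "auroc": self.auroc, "auprc": self.auprc,
        }


@dataclass
class FoldDetail:
    """Per-fold provenance for leakage auditing and downstream reporting."""

    train_records: list[tuple[int, int, int]]
    test_records: list[tuple[int, int, int]]
    graph_edges: set[tuple[int, int]]
    scores: np.ndarray
    labels: np.ndarray
    state: TrainState


@dataclass
class MetricsReport:
    per_fold: list[FoldMetrics]
    details: list[FoldDetail] = field(default_factory=list)

    @property
    def mean(self) -> dict:
        rows = [f.as_row() for f in self.per_fold]
        keys = ("fpr", "tpr", "precision", "recall", "auroc", "auprc")
        return {k: float(np.mean([r[k] for r in rows])) for k in keys}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [f.as_row() for f in self.per_fold]
        mean_row = {"fold": "mean", **{k: "" for k in ("tp", "fp", "tn", "fn")}, **self.mean}
        return pd.DataFrame(rows + [mean_row])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {"folds": [f.as_row() for f in self.per_fold], "mean": self.mean}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def cross_validate(labels: LabeledEdgeSet, expr: ExpressionMatrix, config: RunConfig,
                   permute_labels: bool = False, keep_details: bool = False,
                   log=None) -> MetricsReport:
    """k-fold cross-validation of the edge classifier.

    Negatives are sampled once, mixed with positives and dealt into folds.
    For each fold, the aggregation graph is rebuilt from the *training*
    positives only, the model retrained from scratch (fold-derived seed),
    and the held-out fold scored.  ``permute_labels`` shuffles labels among
    records before splitting — the null-calibration control.
    """
    if config.n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    mixed = sample_negatives(labels, config.neg_ratio, config.seed)
    records = list(mixed.records)
    if permute_labels:
        rng = substream(config.seed, "permute")
        ys = rng.permutation([y for _, _, y in records])
        records = [(i, j, int(y)) for (i, j, _), y in zip(records, ys)]
        mixed = LabeledEdgeSet(records, tf_pool=mixed.tf_pool,
                               target_pool=mixed.target_pool,
                               reference_pairs=mixed.reference_pairs)
    split = make_folds(mixed, config.n_folds, config.seed)
    features = prepare_node_features(expr, log_transform=config.log_transform,
                                     standardize=config.standardize)
    per_fold: list[FoldMetrics] = []
    details: list[FoldDetail] = []
    for fold in range(config.n_folds):
        train_idx = split.train_indices(fold)
        test_idx = split.test_indices(fold)
        train = mixed.subset(train_idx)
        test = mixed.subset(test_idx)
        graph = _graph_from_records(features, expr.n_genes, train.positives,
                                    directed=config.directed_neighbors)
        fold_config = config.with_overrides(seed=(config.seed * 1000 + fold) % (2**31 - 1))
        state = train_model(train, graph, fold_config, log=log)
        preds = predict_edges(state, graph, [(i, j) for i, j, _ in test.records])
        scores = np.array([p for _, _, p in preds])
        ys = np.array([y for _, _, y in test.records])
        c = confusion(scores, ys, config.threshold)
        fpr, tpr, precision, recall = rates(c)
        per_fold.append(FoldMetrics(fold=fold, counts=c, fpr=fpr, tpr=tpr,
                                    precision=precision, recall=recall,
                                    auroc=auroc(scores, ys), auprc=auprc(scores, ys)))
        if keep_details:
            edge_set = set()
            for v, nbrs in enumerate(graph.neighbor_sets):
                edge_set.update((v, u) for u in nbrs)
            details.append(FoldDetail(train_records=train.records,
                                      test_records=test.records,
                                      graph_edges=edge_set, scores=scores,
                                      labels=ys, state=state))
    return MetricsReport(per_fold=per_fold, details=details)


def graph_from_records(features: np.ndarray, n_nodes: int,
                       positive_pairs, directed: bool = False) -> GeneGraph:
    """Aggregation graph from index-level positive pairs (symmetrized by default)."""
    neighbor_sets: list[set[int]] = [set() for _ in range(n_nodes)]
    for i, j in positive_pairs:
        if i == j:
            continue
        neighbor_sets[i].add(j)
        if not directed:
            neighbor_sets[j].add(i)
    return GeneGraph(n_nodes=n_nodes, neighbor_sets=neighbor_sets, node_features=features)


_graph_from_records = graph_from_records
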