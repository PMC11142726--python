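"""Edge-scoring model and training loop.

The scorer treats each pair matrix as a 1-channel 2-D grid and pushes it
through one or three stacked feature-extraction blocks (BatchNorm -> Conv
-> ReLU -> MaxPool).  The flattened outputs of *all* blocks are
concatenated and passed through a lazily-sized fully connected layer, a
ReLU, a final linear layer and a sigmoid, yielding the probability that
the candidate regulator regulates the candidate target.

Geometry note: with the default k=1 the pair matrix has 3 rows, so after
the first 2x2 convolution and pooling the row extent collapses to 1.
Deeper blocks therefore clip their kernel and pool windows per-axis to the
valid extent; an input whose row count is already below the kernel size is
a configuration error.

Training minimizes binary cross-entropy (computed in its saturation-stable
logit form) with momentum SGD under a step-decay schedule:
lr(epoch) = lr0 * decay^floor(epoch / interval).  All model parameters —
SAGE weights, the pooling projection p, and the CNN head — are optimized
jointly, and every random draw descends from the run seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, concat
from .embedding import SageLayer, embed, topk_pool
from .graph import GeneGraph, LabeledEdgeSet, substream
from .io import RunConfig
from .nn import SGD, BatchNorm2d, Conv2d, LazyLinear, MaxPool2d, Module, Parameter
from .pairs import PairFeatureMatrix, assemble_batch_tensor

__all__ = [
    "CnnHead",
    "GrnModel",
    "TrainState",
    "score_pairs",
    "bce_loss",
    "lr_at_epoch",
    "train_model",
    "predict_edges",
    "save_checkpoint",
    "load_checkpoint",
]

_CHANNELS = (16, 32, 64)
_FC_HIDDEN = 256
_CLAMP_EPS = 1e-7


class ConfigurationError(ValueError):
    pass


class CnnHead(Module):
    """Stacked feature-extraction blocks + two fully connected layers + sigmoid."""

    def __init__(self, rows: int, width: int, n_layers: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        if n_layers not in (1, 3):
            raise ConfigurationError("number of feature-extraction layers must be 1 or 3")
        if rows < kernel_size:
            raise ConfigurationError(
                f"pair matrix has {rows} rows, below the convolution kernel size {kernel_size}"
            )
        if width < kernel_size:
            raise ConfigurationError(
                f"embedding width {width} is below the convolution kernel size {kernel_size}"
            )
        self.norms: list[BatchNorm2d] = []
        self.convs: list[Conv2d] = []
        self.pools: list[MaxPool2d] = []
        h, w, c_in = rows, width, 1
        for layer in range(n_layers):
            c_out = _CHANNELS[layer]
            kh, kw = min(kernel_size, h), min(kernel_size, w)
            self.norms.append(BatchNorm2d(c_in))
            self.convs.append(Conv2d(c_in, c_out, kh, kw, rng))
            h, w = h - kh + 1, w - kw + 1
            ph, pw = min(2, h), min(2, w)
            self.pools.append(MaxPool2d(ph, pw))
            h, w = h // ph, w // pw
            c_in = c_out
        self.fc1 = LazyLinear(_FC_HIDDEN, rng)
        self.fc2 = LazyLinear(1, rng)

    def logits(self, x: Tensor) -> Tensor:
        """x: (B, 1, rows, width) -> pre-sigmoid scores (B,)."""
        batch = x.shape[0]
        outputs = []
        h = x
        for bn, conv, pool in zip(self.norms, self.convs, self.pools):
            h = pool(conv(bn(h)).relu())
            outputs.append(h.reshape(batch, -1))
        flat = concat(outputs, axis=1) if len(outputs) > 1 else outputs[0]
        hidden = self.fc1(flat).relu()
        return self.fc2(hidden).reshape(batch)

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, 1, rows, width) -> probabilities (B,)."""
        return self.logits(x).sigmoid()


class GrnModel(Module):
    """SAGE embedding + Top-k pooling + CNN edge scorer, trained end to end."""

    def __init__(self, n_input_features: int, config: RunConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.n_input_features = n_input_features
        dims = [n_input_features] + [config.embed_dim] * config.hops
        self.sage_layers = [
            SageLayer(dims[i], dims[i + 1], config.aggregator, rng)
            for i in range(config.hops)
        ]
        self.pool_p = Parameter(rng.standard_normal(config.embed_dim)) if config.use_topk else None
        rows = config.k_pool + 2 if config.use_topk else 2
        self.head = CnnHead(rows, config.embed_dim, config.cnn_layers,
                            config.kernel_size, rng)

    def forward_logits(self, graph: GeneGraph, pairs,
                       perm_rng: np.random.Generator | None = None) -> Tensor:
        features = Tensor(graph.node_features)
        X = embed(features, graph, self.sage_layers, perm_rng=perm_rng)
        pool = None
        if self.config.use_topk:
            pool = topk_pool(X, self.pool_p, self.config.k_pool, graph,
                             gate=self.config.gate_topk)
        batch = assemble_batch_tensor(X, pool, pairs)
        return self.head.logits(batch)

    def forward(self, graph: GeneGraph, pairs,
                perm_rng: np.random.Generator | None = None) -> Tensor:
        return self.forward_logits(graph, pairs, perm_rng=perm_rng).sigmoid()


@dataclass
class TrainState:
    """Trained (or freshly initialized) model plus its provenance."""

    model: GrnModel
    config: RunConfig
    seed: int
    epoch: int = 0
    lr: float = 0.0
    loss_trace: list[float] = field(default_factory=list)
    gene_ids: list[str] | None = None
    train_records: list[tuple[int, int, int]] | None = None


def score_pairs(e_batch: list[PairFeatureMatrix], head: CnnHead) -> np.ndarray:
    """Score already-assembled pair matrices; all must share one shape."""
    shapes = {m.rows.shape for m in e_batch}
    if len(shapes) != 1:
        raise ValueError(f"pair matrices disagree in shape: {sorted(shapes)}")
    rows, width = shapes.pop()
    x = Tensor(np.stack([m.rows for m in e_batch]).reshape(len(e_batch), 1, rows, width))
    return head(x).data


def bce_loss(predictions, labels) -> Tensor:
    """Mean binary cross-entropy; predictions clamped to [1e-7, 1 - 1e-7]."""
    y_hat = predictions if isinstance(predictions, Tensor) else Tensor(np.asarray(predictions, dtype=np.float64))
    y = np.asarray(labels.data if isinstance(labels, Tensor) else labels, dtype=np.float64)
    if y_hat.shape != y.shape:
        raise ValueError(f"predictions {y_hat.shape} and labels {y.shape} differ in length")
    if y.size == 0:
        raise ValueError("bce_loss requires at least one sample")
    p = y_hat.clip(_CLAMP_EPS, 1.0 - _CLAMP_EPS)
    losses = Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()
    return -losses.mean()


def bce_with_logits(logits: Tensor, labels) -> Tensor:
    """Binary cross-entropy of sigmoid(logits) in the saturation-stable form.

    Identical in value to ``bce_loss(sigmoid(z), y)`` away from the clamp
    (y softplus(-z) + (1-y) softplus(z)), but keeps a useful gradient when
    the sigmoid saturates; used by the training loop.
    """
    y = np.asarray(labels, dtype=np.float64)
    if logits.shape != y.shape:
        raise ValueError(f"logits {logits.shape} and labels {y.shape} differ in length")
    per = Tensor(y) * (-logits).softplus() + Tensor(1.0 - y) * logits.softplus()
    return per.mean()


def lr_at_epoch(epoch: int, lr0: float, decay: float, interval: int) -> float:
    """Step-decay schedule: lr0 * decay^floor(epoch / interval)."""
    if interval < 1:
        raise ValueError("interval must be >= 1")
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return lr0 * decay ** (epoch // interval)


def train_model(train_labels: LabeledEdgeSet, graph: GeneGraph,
                config: RunConfig, log=None) -> TrainState:
    """Jointly optimize SAGE, pooling and CNN-head parameters on labeled edges."""
    records = train_labels.records
    labels = np.array([y for _, _, y in records], dtype=np.float64)
    if len(records) > 0 and len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both positive and negative edges")
    init_rng = substream(config.seed, "model_init")
    model = GrnModel(graph.node_features.shape[1], config, init_rng)
    state = TrainState(model=model, config=config, seed=config.seed)
    if config.epochs == 0:
        model.eval()
        return state
    shuffle_rng = substream(config.seed, "shuffle")
    lstm_rng = substream(config.seed, "lstm_perm") if config.aggregator == "lstm" else None
    pairs = np.array([(i, j) for i, j, _ in records], dtype=np.intp)
    # materialize the lazily-sized FC layers so the optimizer sees every parameter
    model.eval()
    model.forward(graph, pairs[:1], perm_rng=substream(config.seed, "lstm_perm", index=2)
                  if config.aggregator == "lstm" else None)
    optimizer = SGD(model.parameters(), lr=config.lr0, momentum=0.9)
    model.train()
    for epoch in range(config.epochs):
        lr = lr_at_epoch(epoch, config.lr0, config.lr_decay, config.lr_interval_epochs)
        optimizer.lr = lr
        order = shuffle_rng.permutation(len(records))
        total, count = 0.0, 0
        for start in range(0, len(records), config.batch_size):
            batch_idx = order[start : start + config.batch_size]
            logits = model.forward_logits(graph, pairs[batch_idx], perm_rng=lstm_rng)
            loss = bce_with_logits(logits, labels[batch_idx])
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            total += loss.item() * len(batch_idx)
            count += len(batch_idx)
        state.loss_trace.append(total / count)
        state.epoch = epoch + 1
        state.lr = lr
        if log is not None:
            log(f"epoch {epoch:4d}  lr {lr:.6g}  loss {state.loss_trace[-1]:.6f}")
    model.eval()
    return state


def predict_edges(state: TrainState, graph: GeneGraph, pairs,
                  chunk_size: int = 4096) -> list[tuple[int, int, float]]:
    """Score candidate (i, j) pairs in evaluation mode; order-preserving and repeatable."""
    model = state.model
    model.eval()
    pairs = [(int(i), int(j)) for i, j in pairs]
    out: list[tuple[int, int, float]] = []
    for start in range(0, len(pairs), chunk_size):
        chunk = pairs[start : start + chunk_size]
        # fixed-seed permutation stream so repeated calls are identical
        lstm_rng = substream(state.seed, "lstm_perm", index=1) if state.config.aggregator == "lstm" else None
        probs = model.forward(graph, np.asarray(chunk, dtype=np.intp), perm_rng=lstm_rng)
        out.extend((i, j, float(p)) for (i, j), p in zip(chunk, probs.data))
    return out


def save_checkpoint(state: TrainState, path) -> None:
    """Serialize all parameter tensors, buffers, config and provenance."""
    arrays = {f"param:{k}": v for k, v in state.model.named_state().items()}
    meta = {
        "config": state.config.to_dict(),
        "seed": state.seed,
        "epoch": state.epoch,
        "lr": state.lr,
        "loss_trace": state.loss_trace,
        "n_input_features": state.model.n_input_features,
        "gene_ids": state.gene_ids,
        "train_records": state.train_records,
    }
    arrays["meta_json"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def load_checkpoint(path) -> TrainState:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta_json"]))
        params = {k[len("param:"):]: archive[k] for k in archive.files if k.startswith("param:")}
    config = RunConfig(**meta["config"])
    model = GrnModel(meta["n_input_features"], config, substream(meta["seed"], "model_init"))
    model.load_state(params)
    model.eval()
    train_records = meta.get("train_records")
    if train_records is not None:
        train_records = [tuple(r) for r in train_records]
    return TrainState(model=model, config=config, seed=meta["seed"],
                      epoch=meta["epoch"], lr=meta["lr"],
                      loss_trace=list(meta["loss_trace"]), gene_ids=meta["gene_ids"],
                      train_records=train_records)
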