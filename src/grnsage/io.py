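"""File formats and run configuration.

The tool speaks the BEELINE dialects: an ``ExpressionData.csv``-style
gene x cell matrix (gene identifiers as row labels, cell identifiers as the
header row) and a ``refNetwork.csv``-style two-column directed edge list
(``Gene1,Gene2`` = regulator, target).  Ranked predictions are written as a
three-column ``TF,target,score`` table sorted by descending score.

Gene identifiers are case-sensitive exact strings; no symbol normalization
is attempted — silent aliasing is worse than a clean key error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "EdgeList",
    "RunConfig",
    "read_expression",
    "write_expression",
    "read_edge_list",
    "write_edge_list",
    "write_ranked_edges",
    "load_config",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


def _find_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            return item
        seen.add(item)
    return None


@dataclass
class ExpressionMatrix:
    """Gene x cell expression values with identifier labels.

    ``values`` holds non-negative reals (counts or normalized expression);
    row order follows ``gene_ids`` and column order follows ``cell_ids``.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n, m = self.values.shape
        if n < 2 or m < 2:
            raise FormatError(f"expression matrix must be at least 2x2, got {n}x{m}")
        if len(self.gene_ids) != n or len(self.cell_ids) != m:
            raise FormatError("identifier counts do not match matrix shape")
        dup = _find_duplicate(self.gene_ids)
        if dup is not None:
            raise FormatError(f"duplicate gene identifier: {dup!r}")
        dup = _find_duplicate(self.cell_ids)
        if dup is not None:
            raise FormatError(f"duplicate cell identifier: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at gene {self.gene_ids[i]!r}, cell {self.cell_ids[j]!r}"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise FormatError(
                f"negative value at gene {self.gene_ids[i]!r}, cell {self.cell_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class EdgeList:
    """Ordered, directed (regulator, target) identifier pairs."""

    edges: list[tuple[str, str]]

    def __post_init__(self):
        self.edges = [(str(a), str(b)) for a, b in self.edges]
        if len(set(self.edges)) != len(self.edges):
            raise FormatError("duplicate edges in edge list")

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)


_AGGREGATORS = ("mean", "max", "lstm")


@dataclass
class RunConfig:
    """Hyperparameters of the inference pipeline.

    Defaults follow the published operating point: 256-dimensional
    embeddings from a 1-hop MEAN-aggregating SAGE layer, Top-k pooling with
    k=1, a 3-layer stacked CNN with 2x2 kernels, and learning rate 0.01
    decayed to 80% every 10 epochs.
    """

    embed_dim: int = 256
    hops: int = 1
    aggregator: str = "mean"
    k_pool: int = 1
    cnn_layers: int = 3
    use_topk: bool = True
    kernel_size: int = 2
    lr0: float = 0.01
    lr_decay: float = 0.8
    lr_interval_epochs: int = 10
    epochs: int = 100
    batch_size: int = 256
    n_folds: int = 5
    neg_ratio: float = 1.0
    threshold: float = 0.5
    seed: int = 0
    # data-preparation and structural switches
    log_transform: bool = True
    standardize: bool = True
    directed_neighbors: bool = False
    gate_topk: bool = True
    keep_self_loops: bool = False

    def __post_init__(self):
        if self.aggregator not in _AGGREGATORS:
            raise ValueError(f"aggregator must be one of {_AGGREGATORS}, got {self.aggregator!r}")
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be a positive integer")
        if self.hops not in (1, 2, 3):
            raise ValueError("hops must be 1, 2 or 3")
        if self.cnn_layers not in (1, 3):
            raise ValueError("cnn_layers must be 1 or 3")
        if self.k_pool < 0:
            raise ValueError("k_pool must be >= 0")
        if self.k_pool == 0:
            self.use_topk = False
        if not self.use_topk:
            self.k_pool = 0
        if not (0 < self.lr_decay <= 1):
            raise ValueError("lr_decay must lie in (0, 1]")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must lie in (0, 1)")

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML (or flat key: value) config file; kwargs override file values."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"config file {path} must contain a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    raw.update(overrides)
    return RunConfig(**raw)


def read_expression(path: str | Path, delimiter: str = ",") -> ExpressionMatrix:
    """Read a gene x cell matrix (header row = cell ids, first column = gene ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    cell_ids = [str(c) for c in df.columns]
    try:
        values = df.to_numpy(dtype=np.float64)
    except ValueError:
        for i, row in enumerate(df.itertuples(index=False)):
            for j, cell in enumerate(row):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"non-numeric value {cell!r} at gene {gene_ids[i]!r}, "
                        f"cell {cell_ids[j]!r} in {path}"
                    ) from None
        raise
    return ExpressionMatrix(values, gene_ids, cell_ids)


def write_expression(path: str | Path, expr: ExpressionMatrix, delimiter: str = ",") -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.cell_ids)
    df.to_csv(path, sep=delimiter)


def read_edge_list(path: str | Path, delimiter: str = ",",
                   keep_self_loops: bool = False) -> EdgeList:
    """Read a two-column directed edge list (optional ``Gene1,Gene2`` header).

    Duplicate pairs are removed and self-loops dropped (unless
    ``keep_self_loops``); both removals are logged with counts.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(delimiter)]
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected at least two columns, got {len(parts)}")
            a, b = parts[0], parts[1]
            if lineno == 1 and (a.lower(), b.lower()) == ("gene1", "gene2"):
                continue
            pair = (a, b)
            if a == b and not keep_self_loops:
                n_self += 1
                continue
            if pair in seen:
                n_dup += 1
                continue
            seen.add(pair)
            edges.append(pair)
    if n_dup:
        logger.info("read_edge_list: removed %d duplicate edge(s) from %s", n_dup, path)
    if n_self:
        logger.info("read_edge_list: dropped %d self-loop(s) from %s", n_self, path)
    return EdgeList(edges)


def write_edge_list(path: str | Path, edges: EdgeList | Iterable[tuple[str, str]],
                    delimiter: str = ",") -> None:
    with open(path, "w") as fh:
        fh.write(f"Gene1{delimiter}Gene2\n")
        for a, b in edges:
            fh.write(f"{a}{delimiter}{b}\n")


def write_ranked_edges(path: str | Path,
                       records: Iterable[tuple[str, str, float]],
                       delimiter: str = ",") -> None:
    """Write ``TF,target,score`` sorted by score descending, ties by (TF, target)."""
    records = list(records)
    for tf, tg, score in records:
        if not (0.0 <= score <= 1.0):
            raise ValueError(f"score for edge ({tf!r}, {tg!r}) outside [0, 1]: {score}")
    records.sort(key=lambda r: (-r[2], r[0], r[1]))
    with open(path, "w") as fh:
        fh.write(f"TF{delimiter}target{delimiter}score\n")
        for tf, tg, score in records:
            fh.write(f"{tf}{delimiter}{tg}{delimiter}{score:.10g}\n")
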