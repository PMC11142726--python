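"""Planted regulatory networks and simulated expression matrices.

The generator plants a directed TF -> target network with heavy-tailed TF
out-degrees (hub structure, as in curated cell-type-specific reference
networks) and simulates cells in which each TF has an i.i.d. standard
normal activity, each regulated gene is a signed, weighted sum of its
regulators' activities plus Gaussian noise, and every latent value is
mapped through an exponential to a non-negative expression level.  The
map is monotone, so the planted regulator-target dependence survives as a
rank correlation the pipeline can learn — which is exactly what the
package's recovery tests assert.  It is a statistical stand-in for
scRNA-seq, not a kinetic simulator: no dropout, no overdispersion, no
pseudotime.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .graph import substream
from .io import EdgeList, ExpressionMatrix, write_edge_list, write_expression

__all__ = ["PlantedNetwork", "generate_grn", "simulate_expression", "make_fixture", "FIXTURE_PRESET"]

# canonical desk-scale fixture: 100 genes of which 10 TFs, hubby out-degrees
# (mean 5), 200 cells, moderate noise
FIXTURE_PRESET = dict(n_genes=100, n_tfs=10, mean_out_degree=5.0,
                      n_cells=200, noise_sd=0.5, seed=1)


@dataclass
class PlantedNetwork:
    n_genes: int
    n_tfs: int
    edges: list[tuple[int, int]]          # (tf_index, target_index)
    signs: np.ndarray                     # +1 activation / -1 repression per edge
    weights: np.ndarray                   # effect sizes in [0.5, 1.5]
    seed: int

    @property
    def tf_indices(self) -> list[int]:
        return list(range(self.n_tfs))

    def gene_names(self) -> list[str]:
        return [f"TF{i}" if i < self.n_tfs else f"G{i}" for i in range(self.n_genes)]

    def edge_list(self) -> EdgeList:
        names = self.gene_names()
        return EdgeList([(names[i], names[j]) for i, j in self.edges])


def generate_grn(n_genes: int, n_tfs: int, mean_out_degree: float, seed: int) -> PlantedNetwork:
    """Plant a directed TF -> target network with power-law out-degrees.

    Out-degrees are drawn from a rounded power law (exponent 2, truncated at
    n_genes - 1) rescaled so the expected mean matches ``mean_out_degree``;
    targets are drawn uniformly without replacement from the non-TF genes;
    signs are +/-1 with equal probability and weights uniform in [0.5, 1.5].
    The first ``n_tfs`` gene indices are the TFs.
    """
    if not (1 <= n_tfs < n_genes):
        raise ValueError("need 1 <= n_tfs < n_genes")
    max_deg = n_genes - n_tfs  # targets come from the non-TF pool
    if not (1 <= mean_out_degree <= max_deg):
        raise ValueError(
            f"mean_out_degree {mean_out_degree} infeasible: must lie in [1, {max_deg}]"
        )
    rng = substream(seed, "grn")
    # truncated power law with density ~ x^-2 on [1, max_deg]
    raw = (1.0 - rng.uniform(0, 1 - 1.0 / max_deg, size=n_tfs)) ** -1.0
    degrees = np.clip(np.rint(raw * (mean_out_degree / raw.mean())), 1, max_deg).astype(int)
    edges: list[tuple[int, int]] = []
    non_tf = np.arange(n_tfs, n_genes)
    for tf in range(n_tfs):
        targets = rng.choice(non_tf, size=degrees[tf], replace=False)
        edges.extend((tf, int(t)) for t in sorted(targets))
    signs = rng.choice([-1.0, 1.0], size=len(edges))
    weights = rng.uniform(0.5, 1.5, size=len(edges))
    return PlantedNetwork(n_genes=n_genes, n_tfs=n_tfs, edges=edges,
                          signs=signs, weights=weights, seed=seed)


def simulate_expression(net: PlantedNetwork, n_cells: int, noise_sd: float,
                        seed: int) -> ExpressionMatrix:
    """Simulate a gene x cell expression matrix from the planted network.

    Per cell: TF activities ~ N(0,1) i.i.d.; each regulated gene's latent
    value is the signed, weighted sum of its regulators' activities plus
    N(0, noise_sd) noise; unregulated non-TF genes are pure N(0,1) noise.
    Latents pass through exp(x / 2) — monotone, hence Spearman-preserving —
    to yield non-negative expression.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = substream(seed, "expression")
    activities = rng.standard_normal((net.n_tfs, n_cells))
    latent = np.zeros((net.n_genes, n_cells))
    latent[: net.n_tfs] = activities
    regulated = np.zeros(net.n_genes, dtype=bool)
    for (tf, tg), s, w in zip(net.edges, net.signs, net.weights):
        latent[tg] += s * w * activities[tf]
        regulated[tg] = True
    noise = rng.standard_normal((net.n_genes, n_cells))
    for g in range(net.n_tfs, net.n_genes):
        latent[g] += noise[g] * (noise_sd if regulated[g] else 1.0)
    values = np.exp(latent / 2.0)
    return ExpressionMatrix(values, net.gene_names(), [f"C{c}" for c in range(n_cells)])


def make_fixture(out_dir: str | Path | None = None,
                 preset: dict | None = None) -> tuple[ExpressionMatrix, EdgeList]:
    """Build the canonical desk-scale fixture; optionally write the CSV files.

    Regeneration is byte-identical for a given preset.
    """
    p = dict(FIXTURE_PRESET)
    if preset:
        p.update(preset)
    net = generate_grn(p["n_genes"], p["n_tfs"], p["mean_out_degree"], p["seed"])
    expr = simulate_expression(net, p["n_cells"], p["noise_sd"], p["seed"])
    edges = net.edge_list()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_expression(out_dir / "ExpressionData.csv", expr)
        write_edge_list(out_dir / "refNetwork.csv", edges)
    return expr, edges
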