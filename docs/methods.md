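# Methods

## Problem setting

GRN inference is treated as supervised directed link prediction. Inputs
are a gene × cell expression matrix (n genes, m cells, non-negative
values) and a reference edge list of known TF → target interactions.
Genes appearing as sources in the reference network define the TF pool,
genes appearing as targets the target pool; positives are the reference
edges, negatives are sampled uniformly without replacement from
TF × target pairs absent from the reference network (self-pairs
excluded), at ratio 1:1 by default.

## Model

**Node features.** Expression rows are transformed by x → log(1+x) and
then standardized per gene to mean 0, population variance 1 (constant
rows map to zeros). Both steps are switchable; they stabilize the first
linear map from m cells to d embedding dimensions. The aggregation graph
is the undirected (symmetrized) view of the *training* positives —
regulators see targets and vice versa, the common convention for
SAGE-style aggregation; a directed alternative is available
(`directed_neighbors`).

**Embedding.** One SAGE layer per hop (default 1 hop, d = 256):
`h_v ← ReLU(W · concat(h_v, AGG(N(v))))`, with AGG ∈ {mean, elementwise
max, final LSTM state over a seeded random neighbor permutation}. Empty
neighborhoods aggregate to zero. No bias term and no row normalization
are applied — the update is exactly the concatenation form above.

**Top-k pooling.** `vec = ReLU(X p/‖p‖)` with learnable p; the k
highest-scoring nodes are kept (ties broken by lowest node index, making
runs deterministic), their rows gated by `tanh(vec)` so selection remains
differentiable. The adjacency restricted to the selection is computed for
completeness but nothing downstream consumes it; only the selected rows
feed the pair matrices. A switch (`gate_topk=False`) substitutes raw
embedding rows for gated ones.

**Pair matrix and CNN head.** Each candidate edge is the (k+2) × d stack
[h_i; h_j; pooled rows], pooled rows ordered by descending score. The
head applies 1 or 3 feature-extraction blocks (BatchNorm → Conv → ReLU →
MaxPool), channel progression 1 → 16 → 32 → 64, kernel 2×2, pool 2×2.
Geometry: with k = 1 the input has 3 rows; after the first block the row
extent collapses to 1, so deeper blocks clip their kernel and pool
windows per-axis to the valid extent (a 1×2 kernel on a 1-row map). An
input whose row count is already below the kernel size is rejected as a
configuration error. The flattened outputs of *all* blocks are
concatenated into a lazily-sized 256-unit fully connected layer, a ReLU
(inserted as the conventional nonlinearity between the two linear
layers), a final linear layer and a sigmoid.

## Training

Binary cross-entropy over the labeled edges, computed in the
saturation-stable logit form `y·softplus(−z) + (1−y)·softplus(z)` —
mathematically identical to −[y log ŷ + (1−y) log(1−ŷ)] with
ŷ = sigmoid(z), but with useful gradients when the sigmoid saturates.
The reporting-side `bce_loss` clamps probabilities to [1e−7, 1−1e−7]
before the logarithms.

The optimizer is SGD with momentum 0.9 under the step-decay schedule
lr(epoch) = lr0 · decay^⌊epoch/interval⌋ (defaults 0.01, 0.8, 10). Adam
was evaluated first and rejected: its per-coordinate unit-scale first
steps at lr 0.01 swing the ~6000-input fully connected layer's logits by
tens of units, saturating the sigmoid and leaving the head in a dead-ReLU
collapse on desk-scale data. Momentum SGD trains cleanly at exactly the
published schedule, which also keeps the invariant that the applied
learning rate equals the closed form at every epoch.

All parameters — SAGE weights, p, CNN head — are optimized jointly.
Every random draw (negative sampling, fold shuffling, parameter
initialization, batch order, LSTM neighbor permutations) flows from the
run seed through named substreams, so runs are bit-reproducible.
Checkpoints serialize every parameter tensor, batch-norm buffer, the
config and provenance, and round-trip bit-exactly.

The neural network, including reverse-mode automatic differentiation
(dense ops, 2-D convolution, max-pooling, segment max, LSTM), is
implemented in the package on numpy in float64; analytic gradients are
validated against central finite differences in the test suite. Gradient
checks are performed at differentiable points (strictly positive
activations): at ReLU kinks and max-pool ties the subgradient convention
(gradient to the first argmax) legitimately differs from two-sided
differences.

## Evaluation protocol

Negatives are sampled once, mixed with positives, shuffled by seed and
dealt round-robin into n_folds folds (sizes differ by at most one). For
each fold the aggregation graph is rebuilt from the training positives
only — test positives can never leak into the embeddings, which the test
suite asserts by set intersection. The model is retrained from scratch
per fold with a fold-derived seed; fold metrics (confusion at threshold
0.5, FPR/TPR/precision/recall, AUROC, AUPRC) are averaged arithmetically.

AUROC is the tie-aware rank statistic (probability a positive outranks a
negative, ties half); AUPRC is the step-wise sum of precision ×
recall-increment over descending unique thresholds. Both equal brute-force
enumeration by construction and are cross-checked against scikit-learn in
the tests. Zero-denominator rates report 0 with a logged warning.

Evaluated edges are categorized red (true edge predicted positive),
green (true edge missed), blue (non-edge rejected); false positives have
no conventional color and are emitted as "extra". "Evaluated sparsity" is
reported as the fraction of evaluated pairs that are true edges — a
labeled definition, since the quantity has no canonical formula.

## Synthetic benchmark

The generator plants TF → target edges with out-degrees drawn from a
truncated power law (exponent 2), rescaled to a requested mean —
mimicking TF hub structure — with targets drawn uniformly from the
non-TF genes, signs ±1 equiprobable and weights uniform in [0.5, 1.5].
Restricting targets to non-TF genes keeps the simulation well-defined
(a gene is either an exogenous driver or a driven response, never both).
Cells are i.i.d.: TF activities are standard normal, regulated genes are
the signed weighted sum of their regulators' activities plus N(0, noise_sd)
noise, unregulated genes pure N(0,1) noise, and all latents map through
exp(x/2) to non-negative values. The map is monotone, so planted
dependence survives as rank correlation.

The canonical fixture is 100 genes, 10 TFs, mean out-degree 5, 200
cells, noise_sd 0.5, seed 1 (~50 reference edges). What it does *not*
emulate: dropout, overdispersion, library-size variation, pseudotime
dynamics, or TF→TF regulation. Passing recovery tests therefore shows the
pipeline learns planted monotone dependence end to end — not that it
reproduces published performance on real scRNA-seq benchmarks.

## Desk-scale run sizes

Fixture runs train 40 epochs with batch size 16 (the 100-record fixture
needs small batches for enough SGD steps; longer training was evaluated
and does not improve held-out metrics). Recovery is summarized over five
pipeline seeds, null calibration (label permutation) over three to five.
The 20%-training hold-out workflow uses a denser planted benchmark
(100 genes, 20 TFs, ~420 edges, 400 cells): 20% of the 51-edge CV fixture
would leave only ten training positives, too few for an informative
measurement. The library defaults (epochs 100, batch 256) are sized for
benchmark-scale datasets of thousands of labeled edges.

## Known limitations

- The LSTM aggregator processes neighbors sequentially per node; it is
  the slowest path and exists mainly for the ablation grid.
- Full neighborhoods are used (no neighbor subsampling); graphs with
  very high-degree hubs will aggregate over all neighbors.
- Negative sampling is uniform; degree-matched or hard negatives are out
  of scope.
- Pooling indices are discrete: gradients flow through the gates and
  scores, not through the selection itself (the standard Top-k pooling
  behavior).
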