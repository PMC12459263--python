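# Methods

This note records the model, the conventions that the package fixes where
the method description leaves them open, and what the simulation-based
tests do and do not establish.

## Preprocessing

Four steps, applied in order to raw counts:

1. **QC filtering.** Cells expressing (count > 0) fewer than 10 genes are
   removed first; genes expressed in fewer than 3 of the *remaining* cells
   are removed second. The cells-then-genes order matters and is fixed.
   "Expressed" is read as nonzero count, the standard QC semantics; an
   alternative reading (total count < 10) exists but is not used.
2. **Normalization.** Per-cell counts are scaled to a library size of
   10 000 and log1p-transformed.
3. **HVG selection.** 2000 genes by binned normalized dispersion: per-gene
   dispersion = variance/mean on the log-normalized layer, z-scored within
   20 equal-frequency mean-expression bins, ranked descending with ties
   broken by gene ID. Selection is global (one ranking over all cells),
   not per-batch, because the downstream MNN search operates in a single
   shared PCA space.
4. **Scaling and PCA.** Per-gene z-score with the population (1/N)
   standard deviation — chosen so test values are exact — with
   zero-variance genes mapped to zero columns. PCA retains 100 components
   (exact SVD up to 5000 cells, seeded randomized SVD above); each
   component's sign is fixed so its largest-magnitude loading is positive,
   making results reproducible across runs and cell orderings.

## Cross-batch clustering

**Stage 1.** Leiden (RB-configuration quality) per batch on a
shared-nearest-neighbor graph: neighborhoods of size 16 (self + 15
nearest, Euclidean, in the 100-PC space), Jaccard edge weights, pruning
below 1/15. Resolution 3.0 deliberately over-partitions so that rare
subpopulations get their own node in the cluster graph. A degenerate note:
at any resolution above ~1, RB modularity splits a uniform complete graph
(e.g. identical points) into singletons — structureless input therefore
yields singleton clusters at the default resolution, which is harmless
downstream because the cluster graph re-merges them.

**Stage 2.** MNN pairs use cosine distance (1 − cosine similarity; zero
vectors are at distance 1 from everything) on the first 10 PCs. All batch
pairs a ≤ b are searched, so intra-batch (a = b) mutual-kNN pairs are
included — the cluster graph is meant to capture both intra- and
inter-batch relationships; self-neighbors are excluded and unordered pairs
deduplicated.

The expansion step is realized as *deterministic* nearest-neighbor
propagation (the stochastic phrasing "random walk" is implemented with a
fixed transition): at step t each pair (i, j) from step t−1 spawns
(nn1(i), j) and (i, nn1(j)), where nn1 is the within-batch cosine 1-NN;
duplicates and self-pairs are skipped, the union over steps 0..T is
returned, and propagation stops early at a fixed point. T therefore bounds
the propagation radius, and the pair set is monotone in T.

**Cluster graph.** W[c, d] = (#pairs linking c and d) / (|c|·|d|). The
product normalization is the pair-capacity convention; √(|c|·|d|) is
available as `cluster_norm="sqrt"`. Intra-cluster pairs populate the
diagonal under the same rule and act as self-loops.

**Spectral partition.** Symmetric normalized Laplacian
L = I − D^(−1/2) W D^(−1/2); isolated nodes are treated as their own
zero-eigenvalue components. The group count, when not given, is the
position of the largest gap among the first min(20, #nodes) ascending
eigenvalues, floored at the number of connected components (so
disconnected components are never merged). Row-normalized leading
eigenvectors are clustered with seeded k-means (10 restarts). Each cell
inherits its fine cluster's group.

## Batch-correction network

Architecture: two residual blocks at the input width (100), each
FC(d→d) → BN → PReLU → FC(d→d) → BN with the identity skip added after the
second BN and no activation after the add, followed by a linear projection
to the 32-dimensional output. The block width equals the input width so
the skip needs no projection; the five-layer multiset fixes the contents
of a block, and this ordering is the package's choice. The network input
is the 100-PC embedding (the space in which all upstream steps operate),
not scaled expression. Output is left unnormalized and the loss uses raw
Euclidean distance; the loss's angular/margin ancestors exist, but the
form implemented is exactly

    L = log(1 + Σ_{i=1}^{k−1} exp(d(x_a, x_p) − d(x_a, x_{n_i}))),

computed with an overflow-safe log-sum-exp (and log1p on the unshifted
branch so the loss is strictly positive even when the exponentials
underflow). At equal distances L = log(k); it vanishes as negatives move
far away.

Training: tuples of size k = 4 (anchor, one positive from the anchor's
global cluster, three negatives from distinct other clusters; labels are
reused only when fewer than three other clusters exist). The anchor's
cluster is drawn uniformly over clusters with ≥ 2 members, making sampling
class-balanced regardless of cluster sizes. Optimizer: SGD, momentum 0.9,
learning rate 0.01, mini-batch 256 tuples, 50 epochs — the training recipe
is "mini-batch SGD" by specification and these hyperparameters are package
defaults, all exposed in `RunConfig`. Batch norm uses batch statistics
during training and running averages (momentum 0.1) at inference;
inference is deterministic. Distances carry a 1e-12 epsilon inside the
square root so gradients stay defined at coincident points. Backprop is
hand-written and validated against central finite differences (1e-4
relative) in the test suite.

Training requires ≥ 2 global clusters; with one cluster the loss has no
negatives and training is refused with a diagnostic.

## Evaluation metrics

* **ARI** — permutation-model adjusted Rand index from the contingency
  table. (As printed in the source description the expected-index term is
  garbled; the standard formula, cross-checked against scikit-learn at
  1e-10, is used.)
* **NMI** — 2·MI / (H(pred) + H(truth)), natural logs, with conventional
  positive entropies; both-sides-degenerate input returns 1.
* **ASW_celltype** — mean Euclidean silhouette over type labels,
  singleton-type cells scored 0, rescaled to [0, 1] via (mean + 1)/2.
* **iLISI (deviation form)** — per cell, the inverse Simpson index of
  batch proportions among its 90 nearest neighbors (self excluded) is
  compared to N_i, the number of batches containing the cell's type, as
  |iLISI(i) − N_i| / N_i; deviations are averaged within batches, then
  across batches. **Lower is better** (0 = ideal, label-aware mixing).
  Benchmark bar charts elsewhere sometimes plot iLISI as higher-better;
  the deviation definition implemented here is the opposite direction, and
  the package follows the definition, not the chart.
* **BatchKL** — Σ_b p_b log(p_b / q_b) with q the global batch proportions
  and p the proportions among a cell's 100 nearest neighbors, averaged
  over a seeded subsample of ≤ 1000 cells chosen on a cell-ID-sorted
  ordering (so the value is invariant to cell order); zero local
  proportions contribute nothing. The raw value is reported; it is *not*
  pre-normalized to [0, 1].
* **Composites** — Biological_conservation = (ARI + NMI + ASW)/3;
  Batch_mixing = ((3 − BatchKL)/3 + iLISI/3)/2 with BatchKL clipped to
  [0, 3] before use. The formula is applied verbatim; whether its
  constants encode a three-batch normalization is not decidable from the
  definition, so no adjustment is attempted.

The neighborhood sizes (90, 100) are fixed-size kNN choices, configurable,
preferred over perplexity-weighted variants for exact testability.

## Simulation generator

The generator emulates Splatter's structure: gamma base gene means
(shape 0.6, rate 0.3), per-type multiplicative DE factors (probability
0.1, log-normal magnitude exp(±N(1.0, 0.4)), sign equiprobable), per-batch
genome-wide factors (exp(±N(0.15, 0.15))), log-normal library sizes
(ln-mean 9.0, ln-sd 0.25), and negative-binomial counts via a
Gamma–Poisson mixture with BCV 0.1. Type composition per batch is exact
(largest-remainder apportionment), not multinomial. The frozen
"dataset1" fixture is 4 types × 3 batches × 168 cells (2016 cells) × 2000
genes — a clear-separation, visible-batch-effect regime: raw PCA shows
BatchKL ≈ 1.1 before correction.

Not emulated: outlier genes, dropout beyond NB sampling, trajectories,
ambient RNA, doublets, and the long-tailed cluster-size and depth
imbalances of real tissues. A green simulation test therefore establishes
that the machinery recovers planted structure under NB noise and
genome-wide multiplicative batch effects — not performance on any real
dataset.

## Determinism

A single global seed fans out to per-stage seeds (Leiden per batch, k-means
init, tuplet sampling, network init, metric subsampling) via
blake2b(f"{seed}:{stage}") mod 2³¹−1, so stages are individually
re-runnable. Pipelines rerun with the same seed reproduce cluster labels
bitwise and embeddings to ≤ 1e-6. Known non-determinism caveat: exact
floating-point reproducibility across BLAS builds is not guaranteed.

## Limitations

* The corrected output is an embedding; corrected gene-expression values
  are out of scope by design.
* Neighbor searches are exact (O(n²) per batch pair), adequate at desk
  scale (~10⁴ cells); an approximate-NN backend would be needed well
  beyond that.
* The eigengap heuristic can mis-count groups on weakly structured cluster
  graphs; `n_spectral_groups` overrides it.
* Metrics and training assume the global clustering is meaningful; if
  stage 2 merges distinct types, the network will faithfully mix them.
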