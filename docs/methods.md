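# Methods

## Problem setting

Given three binary relationship networks over a shared, closed gene
universe of size n — a symmetric gene–gene (PPI) network `A_PP`, a
bipartite gene–outlying-gene network `A_PO` and a bipartite gene–miRNA
network `A_PR` — plus initial node attributes and a partial labelling of
genes as drivers (1) or non-drivers (0), the model scores every gene's
probability of being a cancer driver. The model is transductive: unlabeled
genes participate in all graph computations but never in any loss or in
the final combiner fit.

## Input attributes

* **Genes** (`X_P`, n × F1): for each of C cancer contexts, a mutation
  rate, a differential-methylation rate and a differential-expression rate
  (3C columns, each min–max normalized to [0, 1]; a constant column maps
  to zeros), concatenated with a 16-dimensional topological embedding of
  `A_PP`. F1 = 64 for C = 16, 19 for C = 1, 28 for the synthetic default
  C = 4. The mutation rate is the fraction of a context's samples in which
  the gene is mutated; methylation and expression rates are accepted as
  precomputed per-context columns — their derivation from raw tumor/normal
  data is upstream of this package.
* **Outlying genes** (`X_O`, m × 2C): per context, the mean expression
  z-score across all of that context's samples and the fraction of samples
  with |z| > 2. A gene is *outlying* if |z| > 2 in at least one sample of
  any context; z-scores are population z-scores computed per gene within a
  context across its tumor samples, and a zero-variance gene gets z = 0
  (never outlying). Note the mean of within-context z-scores is 0 by
  construction when the z-scores are standardized against the same
  samples; the feature is retained for inputs whose z-scores are computed
  against an external reference (as in the synthetic generator), where it
  is informative.
* **miRNAs** (`X_R`, t × F3): per-context mean z-score and mean
  differential expression (2C columns), a similarity block derived from
  the Gaussian Interaction Profile (GIP) kernel over miRNA–disease
  association profiles, and the miRNA's degree in `A_PR`. The GIP kernel
  is `K_ij = exp(−γ‖x_i − x_j‖²)` with the bandwidth scaled by the data,
  `γ = γ'/ mean_i ‖x_i‖²` (γ' = 1); an all-zero profile matrix returns the
  identity. The reduction of K to 16 similarity columns is, by default, a
  trainable affine map owned by whichever model consumes `X_R`
  (`gip_transform: affine`); a fixed truncated-SVD eigen-embedding
  (`gip_transform: svd`) is available when fully deterministic,
  model-independent attribute tables are wanted (the file-export path uses
  it so the written tables are self-contained).

### Topological embedding

The 16-d gene embedding is produced by biased random walks plus skip-gram
with negative sampling (walk length 80, 10 walks per node, window 10,
return and in-out parameters p = q = 1, 5 negatives, 2 epochs). Training
uses mean-gradient minibatch SGD with a linearly decaying learning rate
(0.5) and logit clipping at ±30 — per-pair summed updates are numerically
unstable when the node vocabulary is small. Isolated nodes receive zero
rows. The embedding is seeded from the *dataset's* seed, so attributes are
a property of the dataset, not of a training run.

## Network normalization

All three adjacencies are normalized as
`P_ij = A_ij / √((rowdeg_i + 1)(coldeg_j + 1))`. The +1 degree shift is
applied literally; no self-loop edges are inserted into A. This makes the
transposition identity `P_ji = P_ijᵀ` exact and every division well
defined.

## Architecture

One HGCN layer updates the target side of a network as
`ReLU((P·X_nbr)·θ_k + ((P·X_nbr) ⊙ X_self)·W₁ + b₁)`; the operator
precedence `((P·X_nbr) ⊙ X_self)·W₁` is the only parse that is
dimensionally consistent, and `b₁` is a width-F_out bias broadcast over
nodes. One (θ_k, W₁, b₁) per layer k is shared by all three networks
(L = 2 layers; 256 then 128 filters by default). For bipartite networks
the layer runs in both directions and the two sides alternate roles
between layers; inter-layer dropout is 0.5 during training.

The gene–outlying branch adds the bilinear layer on the *initial*
features: with `s_i = X(i)·W + b` (X the gene's or outlying gene's initial
attributes, the latter lifted to F1 by a learnable affine map), the output
for gene p is the mean of `s_i ⊙ s_j` over unordered pairs of its extended
neighbourhood (outlying neighbours plus p itself), computed by the
identity `½[(Σs)² − Σs²]`; genes with d̃ ≤ 1 get a zero row. `W` maps
directly to the HGCN output width so the convex mixing
`(1−α)·H_P2 + α·H_BA` (α = 0.2) is well defined; a learnable lift path
exists for configurations where the widths differ.

The gene–miRNA branch uses features pre-trained on `A_PR`: a standalone
two-layer HGCN (same widths) trained for 100 epochs by Adam (lr 0.01,
weight decay 5e-4) to reconstruct the bipartite adjacency via inner
products of the final-layer features (lifted back to width F1) with 1:1
negative sampling. Pre-training is unsupervised, runs once per dataset and
is shared across CV folds. The returned feature matrices are rescaled to
unit RMS: the link objective rewards unboundedly large feature norms,
while the downstream interaction terms are *quadratic* in feature scale
per layer, so un-normalized pre-trained features can saturate the output
sigmoids and stall training (saturation zeroes the data gradient and
weight decay then collapses the remaining branches). With
`use_pretrain: false`, the branch falls back to `X_P` and the lifted
`X_R`, trained jointly.

Self-attention (one shared W_Q, W_K, W_V for all three branches,
d = output width, dropout 0.2 on the attention weights, residual
connection) runs over all n genes at once; memory is O(n²), acceptable to
a few tens of thousands of genes. Each branch is reduced to one scalar per
gene by two kernel-size-1 convolutions (hidden width 32, a free choice),
and the stacked branch channels pass one zero-padded 3×3 2D convolution
(channel order fixed as gene–gene, gene–outlying, gene–miRNA; the
convolution is not permutation invariant). The MLP on `X_P` has widths
256, 64, 1.

## Losses and optimization

`L_node` is the mean binary cross-entropy over labelled *training* genes
of sigmoid(H_syn); `L_node1` the same on sigmoid(H_2D); `L_link` is
`−(1/|E|)[Σ_E log â + Σ_Neg log(1−â)]` with `â_ij = sigmoid(⟨h_i, h_j⟩)`
from the branch-1 per-gene scalars, |Neg| = |E| non-edges resampled every
epoch from a seeded stream (never an existing edge or self pair, computed
lazily — the n×n reconstruction is never materialized). Scores are clamped
to [1e-7, 1−1e-7] before logs. The total is
`L_node + ω₁·L_node1 + ω₂·L_link` (ω₁ = 0.1, ω₂ = 0.01); when the
gene–gene network is ablated the link term is dropped. Optimizer: Adam
(lr 0.002, weight decay 0.0005, L2-coupled), full-graph pass per epoch;
default 1065 epochs for a full-scale run, 200 for the synthetic benchmark
(adequate for convergence at that problem size). A non-finite loss aborts
with a diagnostic.

The final combiner is scikit-learn logistic regression (weak L2,
C = 1000) on the five feature columns, fitted per fold on training genes
only and refit in every CV fold; `combiner: sigmoid_sum` bypasses it and
scores genes by sigmoid(H_syn) directly.

## Cross-validation and metrics

Stratified K-fold (default 10; the synthetic benchmark uses 5) over
labelled genes via seeded round-robin assignment, so per-fold class ratios
stay within one gene of the global ratio; every labelled gene is scored
out-of-fold exactly once. AUC is the Mann–Whitney statistic with half
credit for ties; AUPRC is step-wise average precision without
interpolation (both cross-checked against scikit-learn). Reported spreads
across folds are standard deviations, labelled as such.

## Synthetic benchmark

The generator plants driver signal through network topology (two-block
gene–gene model, p_in = 0.10 within drivers vs p_out = 0.02), elevated
bipartite attachment (p_po 0.20/0.05 gated by mutation, p_pr 0.15/0.04),
additive shifts (+0.5) on Beta(2, 10) per-context rate baselines, inflated
z-score variance for driver-linked outlying genes and shifted expression
statistics for driver-linked miRNAs. Defaults: 300 genes, 150 outlying
genes, 60 miRNAs, 4 contexts, 20 samples per context, 15% drivers;
labels = all drivers positive plus an equal-sized random non-driver
negative sample (label_fraction 0.30), remainder unlabeled. These sizes
keep a full 5-fold CV around a minute on one CPU.

What the generator does *not* emulate: real PPI degree distributions
(scale-free hubs), mutation spectra, batch effects, correlated contexts,
or label noise in driver catalogues. Passing the planted-signal tests
demonstrates that the pipeline's machinery recovers a multi-channel signal
end to end — not that it attains any particular accuracy on real cohorts.
On the default conditions the effect sizes are strong enough that
out-of-fold recovery is essentially perfect; the label-permuted control
confirms the pipeline finds nothing when there is nothing to find.

One structural caveat: the link-reconstruction decoder operates on the
per-gene *scalar* 1D features, i.e. a rank-1 model. On a two-block random
graph the only pair-level structure such a decoder can express is block
membership, which caps held-out edge-ranking AUC near 0.54 on the default
benchmark regardless of training; richer generators (e.g. embedding-based
geometric graphs) would be needed for the edge-ranking diagnostic to be
informative. The bipartite pre-training diagnostic does not share this cap
because its decoder works on F1-width features.

## Determinism

Every stochastic component (generation, embedding, initialization,
dropout, negative sampling, fold assignment, the label permutation of the
control) draws from seeds derived via `SeedSequence` from one run seed;
repeated runs are bitwise identical on a fixed thread count.

## Design choices made where the design was open

* Indices are closed universes defined by explicit id sources (the
  attribute tables in the file interface); edge files never create nodes.
  Self-loops in gene–gene edge lists are dropped with a warning.
* Outlying genes keep node identities separate from their gene identities
  (the two roles are disjoint node sets).
* The bilinear layer reads initial features and its output joins the
  branch at the HGCN output width (the mixing equation otherwise adds
  tensors of unequal widths).
* Attention spans all genes in one block (no mini-batching).
* The LR combiner is refit per CV fold, on the training fold only — the
  alternative (one global fit) leaks test labels.
* Dropout is applied between HGCN layers (0.5) and on attention weights
  (0.2) only; pre-training runs without dropout.
* Random-forest / XGBoost combiner variants are not implemented; the
  combiner interface accepts only `lr` and `sigmoid_sum`.

## Known limitations

* Full self-attention and dense branch features make memory O(n²) in the
  gene count; fine to ~20k genes on a workstation, but not beyond.
* The autodiff core is float64 and single-threaded-deterministic; it
  favours reproducibility and auditability over speed. Full-scale runs
  (13k+ genes, 1000+ epochs) are supported but slow compared to
  GPU-framework implementations.
* No identifier mapping between gene symbol systems and no parsing of
  primary database dumps; inputs are plain TSV over pre-mapped ids.
* Genes present in networks but missing from attribute tables are a hard
  error; imputation is the user's responsibility.
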