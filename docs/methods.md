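# Methods

This note records the models, numerical choices, and limitations behind
`tabdeg`, in the order the pipeline runs.

## Labeling model

Counts K_gj for gene g in sample j are modeled as negative binomial with
mean s_j·μ_gc (condition c of sample j) and dispersion α_g, so
Var K = μ + αμ². The labeler is a deliberately transparent approximation
of the DESeq2-style workflow:

- **Expression filter.** Genes with mean value strictly greater than 1
  across all samples are retained. The filter is applied to whichever
  matrix feeds labeling — the count matrix in `label_genes` — and the run
  log records that choice.
- **Size factors** are median-of-ratios: reference genes are those with
  no zero count; s_j = median_g (K_gj / geometric-mean_g). Factors are
  defined up to a common constant; all downstream quantities depend only
  on ratios.
- **Dispersions** are method-of-moments per condition on normalized
  counts, (var − mean)/mean², with the gene's α the maximum over the two
  conditions, clipped to [1e-8, 10]. Taking the maximum is conservative
  (slightly inflates α under the null), which trades a little power for
  fewer false calls. There is no shrinkage across genes, no Cook's
  outlier handling, and no independent filtering: the class boundaries,
  not the test internals, define the method.
- **Wald test.** log2FC = log2((μ̂_T + ε)/(μ̂_N + ε)) with pseudo-mean
  ε = 0.5 normalized counts so estimates stay bounded when one group is
  all zeros. The standard error comes from the delta method under the NB
  variance; the two-sided p-value from the standard normal; adjustment is
  Benjamini–Hochberg over all tested genes. On null simulations the
  rejection rate at p < 0.05 sits in [0.03, 0.07] for large per-group n.
- **Labels.** 1 iff log2FC > 1 and padj < 0.05; 0 iff log2FC < −1 and
  padj < 0.05; else 2. Inequalities are strict.

## Synthetic data

The simulator emulates the data regime the pipeline targets: per-gene
base means log-normal(meanlog 4, sdlog 1.5) (median ≈ 55 counts, heavy
right tail, mimicking bulk RNA-seq dynamic range), per-sample library
size factors log-uniform in [0.5, 2] to exercise the size-factor
estimator, NB dispersion α = 0.1 for every gene, and gene lengths
log-uniform in [500, 100 000] bases for the TPM conversion
(log2(TPM + 0.001)). Planted up-regulated genes multiply the tumor mean
by 2^lfc and down-regulated genes divide by it — symmetric in log space,
matching the labeling rule's symmetry. Default study condition: 2,000
genes, 20 + 20 samples, 10% UR + 10% DR at |log2FC| = 2, chosen so the
planted effect clearly exceeds the labeling threshold.

What the simulator does **not** emulate: batch effects, library-
preparation or GC biases, isoform structure, gene–gene correlation, or
the marginal distributions of any real cohort. Genes are independent
given their parameters. Tests passing on these data therefore establish
internal correctness (the labeler recovers what was planted; the
classifier reproduces the labels) — not performance on real tumor data.

## Feature augmentation

Each gene's features are its expression values across samples, split
into the tumor block and the normal block; all derived statistics are
computed per block.

- **Quantile-to-normal.** Per column (sample), the empirical CDF composed
  with Φ⁻¹ (scikit-learn's `QuantileTransformer`, `n_quantiles =
  min(1000, genes)`). Rank-based, monotone, maps the median to ≈0, and
  clips at the transformer's finite output bounds so no infinities occur;
  invertible on training values up to ties.
- **PCA.** Genes are observations, the block's samples variables.
  Deviation matrix B = X − h uᵀ (u the per-column means), covariance
  C = BᵀB/(M−1), eigendecomposition C = VDVᵀ with eigenpairs in
  decreasing eigenvalue order; scores are the centered rows projected on
  the top p = ⌈0.04·B⌉ eigenvectors (B = block width). Requests beyond
  the covariance rank are truncated with a warning; eigenvector signs are
  fixed (largest-magnitude loading positive) for determinism.
- **Graph embedding.** A k-NN graph (k = 15 by default) with locally
  adaptive exponential weights: per point, weight 1 on the nearest edge
  and scale σ calibrated by bisection so the effective neighbor count is
  log2(k). Directed weights a, b are symmetrized as a + b − ab
  (probabilistic union). Low-dimensional weights are w_l = 1/(1 + d²);
  the 2-D layout minimizes the edge-wise cross entropy by vectorized SGD
  (attraction along edges scaled by w_h, repulsion against 5 sampled
  negatives per edge, linearly decaying step, gradient clipping at 4).
  The initial layout is random normal with scale 10 — spreading the
  start keeps early repulsion gentle. The cross entropy is evaluated on
  the edge set each epoch and the best iterate is returned, so the final
  layout's CE never exceeds the initial one. Out-of-sample rows embed as
  the kernel-weighted mean of their training neighbors' coordinates,
  which is what makes fold-safe cross-validation possible; coordinates
  are not comparable to any other embedding implementation's — only the
  objective and separation behavior are contractual.
- **K-means.** Lloyd's algorithm with k-means++ initialization
  (scikit-learn, fixed `random_state`, 10 restarts) for each K in the
  scan range; K* maximizes VRC_K = (SSB/SSW)·(N−K)/(K−1), with SSW = 0
  giving +∞ and ties resolved toward smaller K. Cluster features are
  one-hot membership plus Euclidean distances to each centroid — a
  categorical and a continuous view; either can be disabled.

**Feature budget.** With B raw columns per block the derived columns per
block number p + 2 + 2K*. The defaults (p = ⌈0.04·B⌉, 2 embedding
dimensions, K scanned over {2, 3}) put the total boost at 16–20% of the
raw column count for B ≈ 50, the regime the defaults are sized for. The
K scan is deliberately narrow: widening it to K ≤ 6 (configurable) can
push the boost past that band because cluster features grow linearly
in K*.

**Transduction vs fold safety.** Fitting the augmentation on all genes at
once leaks held-out genes into the training features (the embedding and
cluster structure see them). The default is therefore fold-safe: all
statistics are fitted on training genes and held-out genes are projected
through `transform`. The transductive behavior remains available as
`paper_mode` and is flagged with a warning in the run log.

## The classifier

A single-decision-step attentive tabular network (wider settings are
configurable):

- input batch norm → feature transformer → attentive mask → masked
  feature transformer → ReLU decision output → linear softmax head;
- feature transformers are GLU blocks (affine → ghost batch norm → gated
  linear unit) with a √0.5-scaled residual; the first affine layer's
  weights are shared between the initial and per-step transformers, but
  every use has its own batch norm, since the unmasked and masked inputs
  have different distributions;
- ghost batch norm computes statistics over virtual batches of 64
  (momentum 0.02 running stats for evaluation mode); with virtual batch
  = batch it reduces exactly to plain batch norm;
- the attentive transformer maps the n_a activations through an affine +
  batch norm, multiplies by the priors, and applies sparsemax (exact
  sorted-threshold simplex projection) or 1.5-entmax (exact closed-form
  threshold; a bisection reference implementation is kept for testing).
  Priors start at 1 and update as P′ = P⊙(γ−M), γ = 1.3 (the customary
  relaxation default; irrelevant at one step but exposed), so with γ = 1
  a fully used feature cannot be selected again;
- the loss is cross entropy against (1−ε) on the true class plus ε/3
  elsewhere, ε = 0.1 by default; λ_sparse = 0 by default, so the mask
  entropy regularizer is off and its recorded contribution is exactly 0;
- training: Adam (2e-2, weight decay 1e-5), learning rate ×0.95 at
  epochs 50/100/150, early stopping on validation log-loss (plain
  log-loss is monitored; the smoothed variant is recorded alongside)
  with patience 50, capped at 200 epochs, best weights restored;
- global feature importance aggregates the per-step masks weighted by
  each row's total positive decision output, summed over the dataset and
  normalized to 1. Per-row attributions are a straightforward variant
  but the dataset aggregate is what is reported;
- optional masked pretraining: cells masked by independent
  Bernoulli(ratio) draws, a GLU + linear decoder reconstructs the masked
  cells (MSE on column-standardized values), and the encoder weights
  warm-start `fit`.

The whole network is float64 numpy on a small reverse-mode autodiff core
(`_autodiff.py`); sparsemax/entmax use hand-derived Jacobians
(J = diag(1_S) − 1_S1_Sᵀ/|S| and J = diag(s) − ssᵀ/Σs with s = √p),
verified against finite differences. Runs are single-threaded-
deterministic: identical data, config, and seed reproduce identical
parameter trajectories, metric tables, and output files byte for byte.

## Evaluation

The outer holdout splits genes 4:1 into train and test, then the train
part 4:1 into train and validation (64/16/20), stratified because the
non-DEG class dominates; unstratified splits can lose a minority class
entirely. Repeated stratified k-fold cross-validation (default 5 folds ×
10 repeats) refits the augmentation per training fold (fold-safe) and
carves an inner validation fifth for early stopping. Metrics are
per-class and macro precision/recall/F1 from the 3×3 confusion matrix,
accuracy, and macro one-vs-rest ROC-AUC (macro rather than weighted,
since single summary values are reported per run; weighted averaging is
a flag away). A class absent from the truth of a fold scores recall 0
with a warning and is skipped in the AUC average.

How the fixed holdout and the repeated CV interact is a genuinely open
design point; the package treats the 4:1 test split as the outer holdout
and runs repeated CV as an independent assessment over the same gene
set, with both results reported.

## Problem sizes in the test suite

The reference study condition for acceptance-style checks is 2,000 genes
with 20 + 20 samples (10% + 10% planted at |log2FC| = 2, α = 0.1); the
augmentation design band is measured at 2,000 genes with 50 + 50
samples. Unit tests use 300–500-gene versions of the same generator and
reduced epoch counts; the network's own tests use a 300-row separable
toy. The end-to-end benchmark trains with the published hyperparameters
capped at 50 epochs, which on these sizes is past the point where
validation loss plateaus.

## Known limitations

- The labeler is not a DESeq2 replacement: no dispersion shrinkage means
  lower power at very small n, and the delta-method Wald statistic is
  asymptotic. The truth labels of the simulator, not DESeq2 parity,
  arbitrate correctness.
- The moment dispersion estimator is noisy below ~5 samples per
  condition (the max over conditions then over-disperses and the test
  becomes conservative).
- The embedding optimizes the printed cross entropy but is a stochastic
  layout; only seeded runs are reproducible.
- The classifier assumes the label-generating thresholds are the target:
  it learns the labeler, including the labeler's mistakes.
- With a single decision step the prior-scaling mechanism is inert
  (priors are computed but never reused); multi-step behavior is
  implemented and unit-tested but not studied.
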