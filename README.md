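# tabdeg

Three-class differential-expression gene classification for two-condition
(tumor vs normal) RNA-seq.

Classical differential-expression (DE) testing labels each gene
up-regulated, down-regulated, or unchanged by fitting a count model per
gene. `tabdeg` implements a two-stage pipeline that turns this into a
supervised learning problem: a negative-binomial Wald labeler produces the
three-class labels, and a sparse-attention tabular network learns to
predict them from each gene's expression profile, augmented with
condition-split dimensionality-reduction and clustering features. The
trained classifier can then be applied to gene expression tables where no
replicated count data (and hence no classical test) is available. A
seeded negative-binomial simulator with planted up-/down-regulated genes
makes every stage testable end to end without any external download.

## The method

**Stage 1 — labeling.** Genes with mean raw count > 1 are retained.
Counts are normalized with median-of-ratios size factors, per-gene NB
dispersions α (variance μ + αμ²) are estimated by method of moments per
condition, and a Wald test on log2(μ_T/μ_N) with delta-method standard
errors yields p-values, adjusted by Benjamini–Hochberg. Labels follow the
standard thresholds:

    label 1 (UR)  ⟺  log2FC >  1  and  padj < 0.05
    label 0 (DR)  ⟺  log2FC < −1  and  padj < 0.05
    label 2 (non-DEG) otherwise

**Stage 2 — augmentation + classification.** Each gene's feature vector
is split into its tumor (T) and normal (N) sample blocks. Per block the
pipeline appends:

- principal-component scores from the eigendecomposition C = VDVᵀ of the
  block covariance;
- 2-D coordinates from a fuzzy k-NN-graph embedding fitted by minimizing
  the edge-wise cross entropy
  CE = Σ_e [w_h log(w_h/w_l) + (1−w_h) log((1−w_h)/(1−w_l))];
- K-means cluster features (one-hot membership + centroid distances),
  with K chosen by the Calinski–Harabasz variance-ratio criterion
  VRC_K = (SSB/SSW)·(N−K)/(K−1).

Raw blocks are quantile-mapped onto a standard normal field; with default
hyperparameters the derived columns add 15–20% on top of the raw columns
for cohorts with ~50 samples per condition. The classifier is an
attentive tabular network: GLU feature transformers with ghost batch
normalization, sparsemax/1.5-entmax feature-selection masks with prior
scaling P′ = P⊙(γ−M), a label-smoothing softmax head, and mask-aggregated
global feature importances (n_d = n_a = 8, one decision step, batch 512,
Adam 2e-2 with ×0.95 milestone decay, early stopping). Evaluation uses a
stratified 64/16/20 train/validation/test split and repeated stratified
k-fold cross-validation with fold-safe (leakage-free) augmentation
refitting; a transductive `paper_mode` is available and flagged in the
run log. Everything runs on the CPU and is deterministic given the seed.

## Worked example

```python
import numpy as np
from tabdeg import (SimulationConfig, simulate_counts, label_genes,
                    build_augmented_dataset, PipelineConfig)
from tabdeg.augment import split_blocks, FeatureAugmenter
from tabdeg.evaluate import make_splits, compute_metrics
from tabdeg.tabnet import TabNetClassifier

# 2,000 genes, 20 tumor + 20 normal samples, 10% UR + 10% DR planted at |log2FC| = 2
ds = simulate_counts(SimulationConfig(seed=7))
labels = label_genes(ds.counts, ds.condition)
print("label counts:", labels.class_counts())

aug = build_augmented_dataset(ds.expression, ds.condition, seed=7)
print(f"features: {aug.n_raw} raw + {aug.n_augmented} augmented")

pos = {g: i for i, g in enumerate(ds.expression.gene_ids)}
expr = ds.expression.subset_genes(np.array([pos[g] for g in labels.gene_ids]))
y, cfg = labels.labels, PipelineConfig(seed=7)
plan = make_splits(len(y), labels, seed=7)
bt, bn = split_blocks(expr, ds.condition)
fa = FeatureAugmenter(cfg.augment, seed=7).fit(bt.values[plan.train], bn.values[plan.train])
E = {k: fa.transform(bt.values[p], bn.values[p], [expr.gene_ids[i] for i in p]).values
     for k, p in (("train", plan.train), ("val", plan.validation), ("test", plan.test))}
clf = TabNetClassifier(cfg.tabnet, seed=7)
clf.fit(E["train"], y[plan.train], E["val"], y[plan.validation], max_epochs=50)
proba = clf.predict_proba(E["test"])
rep = compute_metrics(y[plan.test], proba.argmax(1), proba)
print(f"held-out: accuracy {rep.accuracy:.3f}  macro-F1 {rep.macro_f1:.3f}  "
      f"macro ROC-AUC {rep.roc_auc_macro:.3f}")
```

Output:

```
label counts: {0: 200, 1: 200, 2: 1596}
features: 40 raw + 14 augmented
held-out: accuracy 0.995  macro-F1 0.991  macro ROC-AUC 0.998
```

The labeler recovers essentially all planted genes (200 + 200 of the 400
planted, with the remaining genes labeled non-DEG), and the classifier
reproduces the labels on held-out genes with macro-F1 0.99. On this
20+20-sample cohort the augmented columns add 35% (the 15–20% design band
applies to the ~50-samples-per-condition regime the defaults are sized
for).

The same stages are available from the shell:

```sh
tabdeg simulate --genes 2000 --tumor 20 --normal 20 --seed 7 -o sim/
tabdeg label --counts sim/counts.tsv -o sim/labels.tsv
tabdeg augment --expression sim/expression.tsv -o sim/augmented.tsv
tabdeg run --expression sim/expression.tsv --counts sim/counts.tsv -o run/
```

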