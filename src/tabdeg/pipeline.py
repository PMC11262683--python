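"""End-to-end orchestration: label → augment → train → evaluate.

``run_pipeline`` takes an expression matrix plus either a count matrix
(labels are computed by the NB Wald labeler) or a precomputed label
table, runs the condition-split augmentation, trains the attentive
classifier on the outer 64/16/20 split, runs repeated cross-validation,
and writes the label table, augmented feature table (with provenance
sidecar), metrics report, and feature-importance table.  Identical
config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .augment import AugmentedDataset, FeatureAugmenter, build_augmented_dataset, split_blocks
from .config import PipelineConfig, stage_seed
from .evaluate import CVResult, MetricsReport, compute_metrics, make_splits, repeated_cv
from .io import (
    ConditionPartition,
    CountMatrix,
    ExpressionMatrix,
    GeneLabelTable,
    partition_samples,
    write_labels,
)
from .labeling import label_genes
from .tabnet import TabNetClassifier, TrainedModel

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]

FLOAT_FMT = "%.10g"


@dataclass
class PipelineResult:
    labels: GeneLabelTable
    augmented: AugmentedDataset
    model: TrainedModel
    holdout_metrics: MetricsReport
    cv: CVResult


def run_pipeline(
    config: PipelineConfig,
    expression: ExpressionMatrix,
    counts: CountMatrix | None = None,
    labels: GeneLabelTable | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full pipeline; see the module docstring.

    Either ``counts`` (to compute labels) or ``labels`` must be supplied;
    if both are given the label table takes precedence and the counts are
    ignored with a warning.
    """
    config.validate()
    if counts is None and labels is None:
        raise ValueError("supply either a count matrix or a label table")

    partition = partition_samples(expression.sample_ids, config.tumor_tag, config.normal_tag)

    if labels is not None:
        if counts is not None:
            logger.warning("both labels and counts supplied; using labels, ignoring counts")
    else:
        labels = label_genes(
            counts,
            partition_samples(counts.sample_ids, config.tumor_tag, config.normal_tag),
            config.lfc_threshold,
            config.padj_threshold,
            config.expression_filter,
        )

    # restrict the expression matrix to the labeled gene universe, in label order
    gene_pos = {g: i for i, g in enumerate(expression.gene_ids)}
    missing = [g for g in labels.gene_ids if g not in gene_pos]
    if missing:
        raise ValueError(f"labeled genes absent from expression matrix: {missing[:5]}")
    expression = expression.subset_genes(np.array([gene_pos[g] for g in labels.gene_ids]))

    aug_seed = stage_seed(config.seed, "augment")
    if config.paper_mode:
        logger.warning(
            "paper-mode: transductive augmentation (fit on all genes incl. held-out)"
        )
    augmented = build_augmented_dataset(expression, partition, config, seed=aug_seed)

    y = labels.labels
    plan = make_splits(
        len(y), labels, seed=stage_seed(config.seed, "split"),
        test_fraction=config.test_fraction, val_fraction=config.val_fraction,
    )
    bt, bn = split_blocks(expression, partition)
    if config.paper_mode:
        E_train, E_val, E_test = (augmented.values[p] for p in
                                  (plan.train, plan.validation, plan.test))
        model_feature_names = list(augmented.feature_names)
    else:
        fold_aug = FeatureAugmenter(config.augment, seed=aug_seed).fit(
            bt.values[plan.train], bn.values[plan.train]
        )
        train_ds, val_ds, test_ds = (
            fold_aug.transform(bt.values[p], bn.values[p],
                               [expression.gene_ids[i] for i in p])
            for p in (plan.train, plan.validation, plan.test)
        )
        E_train, E_val, E_test = train_ds.values, val_ds.values, test_ds.values
        model_feature_names = list(train_ds.feature_names)

    clf = TabNetClassifier(config.tabnet, seed=stage_seed(config.seed, "train"))
    clf.fit(E_train, y[plan.train], E_val, y[plan.validation])
    proba = clf.predict_proba(E_test)
    holdout = compute_metrics(y[plan.test], np.argmax(proba, axis=1), proba,
                              config.tabnet.n_classes)
    importance = clf.feature_importances(E_train)
    model = TrainedModel(clf, config.tabnet, clf.history, importance,
                         model_feature_names)
    logger.info("holdout: accuracy %.3f, macro-F1 %.3f", holdout.accuracy, holdout.macro_f1)

    cv = repeated_cv(expression, partition, labels, config)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_labels(labels, outdir / "labels.tsv")
        augmented.to_frame().to_csv(outdir / "augmented.tsv", sep="\t",
                                    index_label="gene_id", float_format=FLOAT_FMT)
        augmented.provenance_frame().to_csv(outdir / "augmented_provenance.tsv",
                                            sep="\t", index=False)
        cv_df = cv.to_frame()
        cv_df.to_csv(outdir / "cv_results.tsv", sep="\t", index=False,
                     float_format=FLOAT_FMT)
        import pandas as pd

        pd.DataFrame([holdout.to_dict()]).to_csv(outdir / "holdout_metrics.tsv", sep="\t",
                                                 index=False, float_format=FLOAT_FMT)
        model.importance_frame().to_csv(outdir / "feature_importance.tsv", sep="\t",
                                        index=False, float_format=FLOAT_FMT)
        config.to_yaml(outdir / "config.yaml")

    return PipelineResult(labels, augmented, model, holdout, cv)
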