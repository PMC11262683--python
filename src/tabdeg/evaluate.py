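"""Splits, metrics, and repeated cross-validation.

The holdout scheme splits genes 4:1 into train and test, then the train
part 4:1 again into train and validation (64/16/20%), stratified by
label because the non-DEG class dominates.  Repeated stratified k-fold
cross-validation (default 5 folds × 10 repeats) refits the feature
augmentation inside each training fold (leakage-free) unless the
transductive ``paper_mode`` is requested, in which case the augmentation
statistics include held-out genes and the run log flags it.

Metrics are per-class and macro precision/recall/F1 from the 3×3
confusion matrix, overall accuracy, and macro one-vs-rest ROC-AUC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .augment import FeatureAugmenter, split_blocks
from .config import PipelineConfig, stage_seed
from .io import ConditionPartition, ExpressionMatrix, GeneLabelTable
from .tabnet import TabNetClassifier

logger = logging.getLogger(__name__)

__all__ = ["SplitPlan", "MetricsReport", "CVResult", "make_splits", "compute_metrics",
           "repeated_cv"]


@dataclass
class SplitPlan:
    """Disjoint train/validation/test gene-index sets (≈64/16/20%)."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        parts = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(p) for p in parts)
        union = set().union(*parts)
        if total != len(union):
            raise ValueError("split parts overlap")


@dataclass
class MetricsReport:
    """Per-class and macro classification metrics."""

    accuracy: float
    precision: np.ndarray      # per class (0, 1, 2)
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    roc_auc_macro: float
    per_class_auc: np.ndarray | None = None

    def to_dict(self) -> dict[str, float]:
        d = {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "roc_auc_macro": self.roc_auc_macro,
        }
        for c in range(len(self.precision)):
            d[f"precision_{c}"] = float(self.precision[c])
            d[f"recall_{c}"] = float(self.recall[c])
            d[f"f1_{c}"] = float(self.f1[c])
        return d


@dataclass
class CVResult:
    """One MetricsReport per (repeat, fold), with mean ± sd summaries."""

    reports: list[tuple[int, int, MetricsReport]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for repeat, fold, rep in self.reports:
            row = {"repeat": repeat, "fold": fold}
            row.update(rep.to_dict())
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        df = self.to_frame().drop(columns=["repeat", "fold"])
        return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1 if len(df) > 1 else 0)})


def make_splits(
    n_genes: int,
    labels: GeneLabelTable | np.ndarray,
    seed: int = 0,
    test_fraction: float = 0.2,
    val_fraction: float = 0.2,
) -> SplitPlan:
    """Stratified 4:1 test split followed by a 4:1 validation split.

    Every class must have at least enough members to stratify both splits.
    """
    y = labels.labels if isinstance(labels, GeneLabelTable) else np.asarray(labels)
    if len(y) != n_genes:
        raise ValueError("labels length must equal n_genes")
    if n_genes < 25:
        raise ValueError("need at least 25 genes to split 64/16/20")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 5:
        small = classes[counts.argmin()]
        raise ValueError(f"class {small} has only {counts.min()} members; cannot stratify")
    idx = np.arange(n_genes)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=y
    )
    train_idx, val_idx = train_test_split(
        train_idx, test_size=val_fraction, random_state=seed + 1, stratify=y[train_idx]
    )
    return SplitPlan(np.sort(train_idx), np.sort(val_idx), np.sort(test_idx), seed)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    probabilities: np.ndarray | None = None,
    n_classes: int = 3,
) -> MetricsReport:
    """Confusion-matrix metrics plus macro one-vs-rest ROC-AUC.

    A class absent from ``y_true`` gets recall 0 with a warning and is
    skipped in the AUC macro average.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    labels = list(range(n_classes))
    present = np.unique(y_true)
    for c in labels:
        if c not in present:
            warnings.warn(f"class {c} absent from y_true; its recall is reported as 0")
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    cm = _confusion(y_true, y_pred, n_classes)
    accuracy = float(np.trace(cm) / cm.sum())

    auc_macro = np.nan
    per_class_auc = None
    if probabilities is not None:
        probabilities = np.asarray(probabilities)
        if probabilities.shape != (len(y_true), n_classes):
            raise ValueError("probabilities must be (n, n_classes)")
        if not np.allclose(probabilities.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")
        per_class_auc = np.full(n_classes, np.nan)
        for c in labels:
            pos = y_true == c
            if pos.any() and (~pos).any():
                per_class_auc[c] = roc_auc_score(pos, probabilities[:, c])
        valid = ~np.isnan(per_class_auc)
        auc_macro = float(per_class_auc[valid].mean()) if valid.any() else np.nan
    return MetricsReport(
        accuracy=accuracy,
        precision=prec,
        recall=rec,
        f1=f1,
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
        roc_auc_macro=auc_macro,
        per_class_auc=per_class_auc,
    )


def _fit_and_score(
    expression: ExpressionMatrix,
    partition: ConditionPartition,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: PipelineConfig,
    seed: int,
    paper_mode: bool,
) -> MetricsReport:
    bt, bn = split_blocks(expression, partition)
    if paper_mode:
        logger.warning(
            "paper-mode augmentation: statistics fitted on ALL genes, including "
            "held-out test genes (transductive; not leakage-free)"
        )
        aug = FeatureAugmenter(config.augment, seed=seed).fit(bt.values, bn.values)
    else:
        aug = FeatureAugmenter(config.augment, seed=seed).fit(
            bt.values[train_idx], bn.values[train_idx]
        )
    E_train = aug.transform(bt.values[train_idx], bn.values[train_idx],
                            [expression.gene_ids[i] for i in train_idx]).values
    E_test = aug.transform(bt.values[test_idx], bn.values[test_idx],
                           [expression.gene_ids[i] for i in test_idx]).values
    # carve a stratified validation subset out of the training genes
    tr, val = train_test_split(
        np.arange(len(train_idx)), test_size=config.val_fraction,
        random_state=seed, stratify=y[train_idx],
    )
    clf = TabNetClassifier(config.tabnet, seed=seed)
    clf.fit(E_train[tr], y[train_idx][tr], E_train[val], y[train_idx][val])
    proba = clf.predict_proba(E_test)
    return compute_metrics(y[test_idx], np.argmax(proba, axis=1), proba,
                           config.tabnet.n_classes)


def repeated_cv(
    expression: ExpressionMatrix,
    partition: ConditionPartition,
    labels: GeneLabelTable,
    config: PipelineConfig,
    paper_mode: bool | None = None,
) -> CVResult:
    """Repeated stratified k-fold cross-validation over genes.

    Per repeat × fold: fit the augmenters (on training genes unless
    ``paper_mode``) and the classifier on the training genes with an inner
    validation subset for early stopping, then score the held-out fold.
    """
    config.validate()
    if list(labels.gene_ids) != list(expression.gene_ids):
        raise ValueError("labels and expression must cover the same genes in order")
    paper_mode = config.paper_mode if paper_mode is None else paper_mode
    y = labels.labels
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < config.folds:
        raise ValueError(
            f"class {classes[counts.argmin()]} has fewer members than folds"
        )
    result = CVResult()
    for repeat in range(config.repeats):
        rep_seed = stage_seed(config.seed, f"cv-repeat-{repeat}")
        skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=rep_seed)
        for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
            try:
                report = _fit_and_score(
                    expression, partition, y, train_idx, test_idx, config,
                    seed=rep_seed + fold, paper_mode=paper_mode,
                )
            except Exception as exc:
                raise RuntimeError(f"repeat {repeat}, fold {fold} failed: {exc}") from exc
            result.reports.append((repeat, fold, report))
    return result
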