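"""Three-class differential-expression labeling.

A deliberately transparent negative-binomial Wald pipeline in the DESeq2
tradition: low-expression filtering, median-of-ratios size factors,
method-of-moments dispersions, a per-gene Wald test on the tumor/normal
mean ratio, Benjamini–Hochberg adjustment, and threshold-based label
assignment (label 1 = up-regulated, 0 = down-regulated, 2 = non-DEG).

This is not a DESeq2 re-implementation: there is no dispersion shrinkage,
no Cook's-distance outlier handling and no independent filtering.  The
class boundaries — |log2FC| > 1 and padj < 0.05 — define the labels; the
test behind them is a plain delta-method Wald statistic under the NB
variance μ + αμ².
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ConditionPartition, CountMatrix, ExpressionMatrix, GeneLabelTable

logger = logging.getLogger(__name__)

__all__ = [
    "SizeFactors",
    "DispersionEstimates",
    "DEResult",
    "filter_low_expression",
    "estimate_size_factors",
    "estimate_dispersions",
    "nb_wald_test",
    "assign_labels",
    "label_genes",
]

DISPERSION_FLOOR = 1e-8
DISPERSION_CEIL = 10.0
LFC_PSEUDO_MEAN = 0.5  # normalized-count offset keeping log2FC bounded for zero groups


@dataclass
class SizeFactors:
    """Per-sample median-of-ratios normalization constants."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(~np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("size factors must be finite and positive")


@dataclass
class DispersionEstimates:
    """Per-gene NB dispersion α (variance = μ + αμ²), clipped to [1e-8, 10]."""

    gene_ids: list[str]
    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if np.any(self.alpha < DISPERSION_FLOOR - 1e-15) or np.any(self.alpha > DISPERSION_CEIL):
            raise ValueError("dispersions out of [1e-8, 10]")


@dataclass
class DEResult:
    """Per-gene Wald-test results for the tumor-vs-normal contrast."""

    gene_ids: list[str]
    base_mean: np.ndarray
    log2fc: np.ndarray
    se: np.ndarray
    wald: np.ndarray
    pvalue: np.ndarray
    padj: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "baseMean": self.base_mean,
                "log2FC": self.log2fc,
                "lfcSE": self.se,
                "stat": self.wald,
                "pvalue": self.pvalue,
                "padj": self.padj,
            }
        )


def filter_low_expression(matrix, threshold: float = 1.0):
    """Retain genes whose mean value across all samples is strictly > threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    values = matrix.counts if isinstance(matrix, CountMatrix) else matrix.values
    keep = np.flatnonzero(values.mean(axis=1) > threshold)
    if keep.size == 0:
        raise ValueError("expression filter removed every gene")
    logger.info("expression filter (> %g): kept %d of %d genes", threshold, keep.size,
                values.shape[0])
    return matrix.subset_genes(keep)


def estimate_size_factors(counts: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    Reference genes are those with no zero count; s_j is the median over
    reference genes of counts_gj / geometric-mean_g.
    """
    c = counts.counts.astype(float)
    ref = np.all(c > 0, axis=1)
    if not ref.any():
        raise ValueError("no gene has all-positive counts; cannot estimate size factors")
    logc = np.log(c[ref])
    log_geomean = logc.mean(axis=1)
    s = np.exp(np.median(logc - log_geomean[:, None], axis=0))
    return SizeFactors(list(counts.sample_ids), s)


def _condition_indices(counts: CountMatrix, partition: ConditionPartition):
    idx = {sid: j for j, sid in enumerate(counts.sample_ids)}
    t = np.array([idx[s] for s in partition.tumor_samples])
    n = np.array([idx[s] for s in partition.normal_samples])
    return t, n


def estimate_dispersions(
    counts: CountMatrix, s: SizeFactors, partition: ConditionPartition
) -> DispersionEstimates:
    """Method-of-moments dispersions on size-factor-normalized counts.

    Per gene, each condition contributes (var − mean) / mean²; the gene's
    α is the larger of the two, clipped to [1e-8, 10].
    """
    t_idx, n_idx = _condition_indices(counts, partition)
    if t_idx.size < 2 or n_idx.size < 2:
        raise ValueError("dispersion estimation requires >= 2 samples per condition")
    q = counts.counts / s.values[None, :]
    alpha = np.full(counts.n_genes, DISPERSION_FLOOR)
    for idx in (t_idx, n_idx):
        m = q[:, idx].mean(axis=1)
        v = q[:, idx].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m) / np.maximum(m, 1e-300) ** 2, DISPERSION_FLOOR)
        alpha = np.maximum(alpha, a)
    alpha = np.clip(alpha, DISPERSION_FLOOR, DISPERSION_CEIL)
    return DispersionEstimates(list(counts.gene_ids), alpha)


def nb_wald_test(
    counts: CountMatrix,
    s: SizeFactors,
    dispersions: DispersionEstimates,
    partition: ConditionPartition,
) -> DEResult:
    """Per-gene Wald test of the tumor/normal normalized-mean ratio.

    log2FC = log2((μ_T + ε) / (μ_N + ε)) with ε = 0.5; its standard error
    comes from the delta method under Var(K_ij) = s_j μ + α s_j² μ², and
    the two-sided p-value from the standard normal.  padj is
    Benjamini–Hochberg across all tested genes.
    """
    if counts.n_genes == 0:
        raise ValueError("no genes to test")
    t_idx, n_idx = _condition_indices(counts, partition)
    q = counts.counts / s.values[None, :]
    alpha = dispersions.alpha
    eps = LFC_PSEUDO_MEAN

    mu_t = q[:, t_idx].mean(axis=1)
    mu_n = q[:, n_idx].mean(axis=1)
    log2fc = np.log2((mu_t + eps) / (mu_n + eps))

    # Var(mean of normalized counts) = (1/n²) Σ_j (μ/s_j + αμ²)
    inv_s_t = (1.0 / s.values[t_idx]).sum()
    inv_s_n = (1.0 / s.values[n_idx]).sum()
    var_t = (mu_t * inv_s_t + alpha * mu_t**2 * t_idx.size) / t_idx.size**2
    var_n = (mu_n * inv_s_n + alpha * mu_n**2 * n_idx.size) / n_idx.size**2
    se = np.sqrt(var_t / (mu_t + eps) ** 2 + var_n / (mu_n + eps) ** 2) / np.log(2)
    se = np.maximum(se, 1e-12)

    wald = log2fc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(wald))
    padj = multipletests(pvalue, method="fdr_bh")[1]
    base_mean = q.mean(axis=1)
    return DEResult(list(counts.gene_ids), base_mean, log2fc, se, wald, pvalue, padj)


def assign_labels(
    de: DEResult, lfc_threshold: float = 1.0, padj_threshold: float = 0.05
) -> GeneLabelTable:
    """Threshold the test results into the three classes.

    label 1 ⟺ log2FC > threshold and padj < padj_threshold;
    label 0 ⟺ log2FC < −threshold and padj < padj_threshold;
    label 2 otherwise.  Inequalities are strict.
    """
    if lfc_threshold <= 0 or padj_threshold <= 0:
        raise ValueError("thresholds must be > 0")
    sig = de.padj < padj_threshold
    labels = np.full(len(de.gene_ids), 2, dtype=np.int64)
    labels[(de.log2fc > lfc_threshold) & sig] = 1
    labels[(de.log2fc < -lfc_threshold) & sig] = 0
    return GeneLabelTable(list(de.gene_ids), labels, de.log2fc, de.padj, de.pvalue)


def label_genes(
    counts: CountMatrix,
    partition: ConditionPartition,
    lfc_threshold: float = 1.0,
    padj_threshold: float = 0.05,
    expression_filter: float = 1.0,
) -> GeneLabelTable:
    """Full labeling pipeline: filter → size factors → dispersions → Wald → labels.

    The expression filter is applied to the count matrix feeding the test
    (mean raw count strictly above the threshold).
    """
    logger.info("labeling: expression filter applied to the count matrix (mean count > %g)",
                expression_filter)
    filtered = filter_low_expression(counts, expression_filter)
    s = estimate_size_factors(filtered)
    disp = estimate_dispersions(filtered, s, partition)
    de = nb_wald_test(filtered, s, disp, partition)
    return assign_labels(de, lfc_threshold, padj_threshold)
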