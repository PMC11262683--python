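"""Two-condition negative-binomial RNA-seq simulation.

Emulates the data regime the pipeline is built for: a gene × sample count
matrix from a tumor group and a normal group, with a fraction of genes
planted as up-regulated (tumor mean = 2^lfc × normal mean) or
down-regulated (the reciprocal), per-gene dispersions, per-sample library
size factors, and gene lengths for the TPM conversion.  Truth labels are
recorded by construction, so every downstream stage can be validated
without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig
from .io import ConditionPartition, CountMatrix, ExpressionMatrix, GeneLabelTable

__all__ = ["SyntheticDataset", "simulate_counts", "counts_to_expression"]

LOG_TPM_OFFSET = 0.001  # expression scale is log2(TPM + 0.001)


@dataclass
class SyntheticDataset:
    counts: CountMatrix
    expression: ExpressionMatrix
    truth: GeneLabelTable
    condition: ConditionPartition
    base_means: np.ndarray
    size_factors: np.ndarray


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB with variance μ + αμ² (α = 0 degenerates to Poisson)."""
    if alpha <= 0:
        return rng.poisson(mean)
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_counts(config: SimulationConfig) -> SyntheticDataset:
    """Draw a seeded two-condition NB count matrix with planted DEGs.

    counts[g, s] ~ NB(mean = base_mean_g × fold_g(condition_s) × libsize_s,
    dispersion α).  UR genes (truth label 1) multiply the tumor mean by
    2^lfc; DR genes (label 0) divide it; all remaining genes (label 2)
    share the same mean in both conditions.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, nT, nN = config.n_genes, config.n_tumor, config.n_normal

    base = rng.lognormal(config.base_mean_meanlog, config.base_mean_sdlog, size=G)
    lengths = np.exp(rng.uniform(np.log(config.length_low), np.log(config.length_high), size=G))
    libsize = np.exp(rng.uniform(np.log(config.libsize_low), np.log(config.libsize_high),
                                 size=nT + nN))

    n_ur = int(round(config.frac_ur * G))
    n_dr = int(round(config.frac_dr * G))
    labels = np.full(G, 2, dtype=np.int64)
    order = rng.permutation(G)
    labels[order[:n_ur]] = 1
    labels[order[n_ur:n_ur + n_dr]] = 0

    fold = 2.0 ** config.lfc_magnitude
    tumor_mean = base * np.where(labels == 1, fold, np.where(labels == 0, 1.0 / fold, 1.0))
    normal_mean = base

    mu = np.empty((G, nT + nN))
    mu[:, :nT] = tumor_mean[:, None] * libsize[None, :nT]
    mu[:, nT:] = normal_mean[:, None] * libsize[None, nT:]
    counts = _nb_draw(rng, mu, config.dispersion)

    gene_ids = [f"G{i:05d}" for i in range(G)]
    tumor_ids = [f"SIM-T{i:03d}-01A" for i in range(nT)]
    normal_ids = [f"SIM-N{i:03d}-11A" for i in range(nN)]
    cm = CountMatrix(gene_ids, tumor_ids + normal_ids, counts, lengths)
    truth = GeneLabelTable(
        gene_ids,
        labels,
        np.where(labels == 1, config.lfc_magnitude,
                 np.where(labels == 0, -config.lfc_magnitude, 0.0)),
        np.where(labels == 2, 1.0, 0.0),
    )
    return SyntheticDataset(
        counts=cm,
        expression=counts_to_expression(cm),
        truth=truth,
        condition=ConditionPartition(tumor_ids, normal_ids),
        base_means=base,
        size_factors=libsize,
    )


def counts_to_expression(counts: CountMatrix) -> ExpressionMatrix:
    """Convert counts to the log2(TPM + 0.001) expression scale.

    Per sample, TPM_g = 1e6 · (count_g / length_g) / Σ_g' (count_g' / length_g').
    """
    if counts.gene_lengths is None:
        raise ValueError("gene_lengths are required for TPM conversion")
    rate = counts.counts / counts.gene_lengths[:, None]
    total = rate.sum(axis=0)
    if np.any(total <= 0):
        bad = [counts.sample_ids[j] for j in np.flatnonzero(total <= 0)]
        raise ValueError(f"TPM undefined for all-zero samples: {bad[:5]}")
    tpm = 1e6 * rate / total[None, :]
    return ExpressionMatrix(
        list(counts.gene_ids), list(counts.sample_ids), np.log2(tpm + LOG_TPM_OFFSET)
    )
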