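"""Run configuration.

One root seed drives the whole pipeline; each stage draws its own child
seed from a ``numpy.random.SeedSequence`` spawn so that stages are
independently reproducible.  Config round-trips through YAML and is
mirrored by CLI flags.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["AugmentConfig", "TabNetConfig", "SimulationConfig", "PipelineConfig", "stage_seed"]


@dataclass
class AugmentConfig:
    """Hyperparameters of the condition-split feature augmentation.

    The per-block feature budget is chosen so that, on a typical
    two-condition cohort (tens of samples per condition), the augmented
    columns add 15–20% on top of the raw columns: ``pca_fraction`` of the
    block width in principal components, a 2-D graph embedding, and a
    cluster scan over a small K range contributing one-hot membership plus
    centroid distances.
    """

    pca_fraction: float = 0.04      # components per block = ceil(fraction * block width)
    embed_dim: int = 2
    n_neighbors: int = 15
    embed_epochs: int = 100
    negative_samples: int = 5
    k_min: int = 2
    k_max: int = 3
    cluster_onehot: bool = True
    cluster_distance: bool = True

    def validate(self) -> None:
        if not (0 < self.pca_fraction <= 1):
            raise ValueError("pca_fraction must be in (0, 1]")
        if self.embed_dim < 1 or self.n_neighbors < 2 or self.embed_epochs < 1:
            raise ValueError("embedding hyperparameters out of range")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("cluster K range must satisfy 2 <= k_min <= k_max")


@dataclass
class TabNetConfig:
    """Attentive tabular network hyperparameters (training-schedule defaults
    follow the published configuration: n_d = n_a = 8, a single decision
    step, entmax masks, batch 512 with ghost batch norm over virtual
    batches of 64, Adam at 2e-2 decayed ×0.95 at epochs 50/100/150,
    early stopping with patience 50 capped at 200 epochs)."""

    n_d: int = 8
    n_a: int = 8
    n_steps: int = 1
    gamma: float = 1.3              # prior relaxation across decision steps
    lambda_sparse: float = 0.0
    mask_type: str = "entmax15"     # or "sparsemax"
    batch_size: int = 512
    virtual_batch_size: int = 64
    max_epochs: int = 200
    patience: int = 50
    learning_rate: float = 2e-2
    weight_decay: float = 1e-5
    milestones: tuple[int, ...] = (50, 100, 150)
    lr_decay: float = 0.95
    label_smoothing: float = 0.1
    n_classes: int = 3
    momentum: float = 0.02          # batch-norm running-stat momentum

    def validate(self) -> None:
        if self.n_d < 1 or self.n_a < 1 or self.n_steps < 1:
            raise ValueError("n_d, n_a, n_steps must be >= 1")
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")
        if not (0 <= self.label_smoothing < 1):
            raise ValueError("label_smoothing must be in [0, 1)")
        if self.virtual_batch_size > self.batch_size:
            raise ValueError("virtual_batch_size must be <= batch_size")
        if self.mask_type not in ("sparsemax", "entmax15"):
            raise ValueError("mask_type must be 'sparsemax' or 'entmax15'")


@dataclass
class SimulationConfig:
    """Two-condition negative-binomial count simulation with planted
    up-/down-regulated genes.

    Counts are NB with variance μ + αμ² (mean/dispersion convention).
    Per-gene base means are log-normal (meanlog 4, sdlog 1.5) to mimic the
    dynamic range of bulk RNA-seq; library size factors are log-uniform in
    [0.5, 2]; gene lengths log-uniform in [5e2, 1e5] bases for TPM.
    """

    n_genes: int = 2000
    n_tumor: int = 20
    n_normal: int = 20
    frac_ur: float = 0.1
    frac_dr: float = 0.1
    lfc_magnitude: float = 2.0
    base_mean_meanlog: float = 4.0
    base_mean_sdlog: float = 1.5
    dispersion: float = 0.1
    libsize_low: float = 0.5
    libsize_high: float = 2.0
    length_low: float = 5e2
    length_high: float = 1e5
    seed: int = 0

    def validate(self) -> None:
        if self.frac_ur < 0 or self.frac_dr < 0 or self.frac_ur + self.frac_dr >= 1:
            raise ValueError("frac_ur + frac_dr must be < 1 with both >= 0")
        if min(self.n_genes, self.n_tumor, self.n_normal) < 1:
            raise ValueError("n_genes, n_tumor, n_normal must be positive")
        if self.lfc_magnitude <= 0 or self.dispersion < 0:
            raise ValueError("lfc_magnitude must be > 0 and dispersion >= 0")
        if not (0 < self.libsize_low <= self.libsize_high):
            raise ValueError("library size bounds must be positive and ordered")


@dataclass
class PipelineConfig:
    """End-to-end run configuration: labeling thresholds, augmentation,
    network, and evaluation scheme (outer 4:1 test split, then 4:1
    validation; stratified k-fold CV with repeats)."""

    lfc_threshold: float = 1.0
    padj_threshold: float = 0.05
    expression_filter: float = 1.0
    tumor_tag: str = "01A"
    normal_tag: str = "11A"
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    tabnet: TabNetConfig = field(default_factory=TabNetConfig)
    test_fraction: float = 0.2
    val_fraction: float = 0.2
    folds: int = 5
    repeats: int = 10
    paper_mode: bool = False        # transductive augmentation (leaks test genes)
    seed: int = 0

    def validate(self) -> None:
        if self.lfc_threshold <= 0 or self.padj_threshold <= 0:
            raise ValueError("labeling thresholds must be > 0")
        if not (0 < self.test_fraction < 1) or not (0 < self.val_fraction < 1):
            raise ValueError("split fractions must be in (0, 1)")
        if self.folds < 2 or self.repeats < 1:
            raise ValueError("folds must be >= 2 and repeats >= 1")
        self.augment.validate()
        self.tabnet.validate()

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["tabnet"]["milestones"] = list(self.tabnet.milestones)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        aug = AugmentConfig(**d.pop("augment", {}))
        tn = d.pop("tabnet", {})
        if "milestones" in tn:
            tn["milestones"] = tuple(tn["milestones"])
        cfg = cls(augment=aug, tabnet=TabNetConfig(**tn), **d)
        cfg.validate()
        return cfg


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed derived from the root seed."""
    ss = np.random.SeedSequence([root_seed, int.from_bytes(stage.encode(), "little") % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))
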