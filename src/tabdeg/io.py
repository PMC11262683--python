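"""Tabular I/O and sample partitioning.

Gene × sample matrices are stored as plain delimited text: a header row of
sample identifiers and a first column of gene identifiers.  TSV is the
default dialect; commas are auto-detected.  Two-condition runs derive the
tumor/normal partition from TCGA-style specimen suffixes in the sample
names ("01A" → tumor, "11A" → normal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "CountMatrix",
    "ConditionPartition",
    "GeneLabelTable",
    "read_matrix",
    "write_matrix",
    "partition_samples",
    "read_labels",
    "write_labels",
]


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what} ids: {dupes[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """Log-scale expression values (e.g. log2(TPM + 0.001)), genes × samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes × {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in keep], list(self.sample_ids), self.values[keep]
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, idx])


@dataclass
class CountMatrix:
    """Raw read counts, genes × samples, with optional gene lengths for TPM."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    gene_lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("count matrix shape does not match id lists")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integral")
        self.counts = np.asarray(np.round(counts), dtype=np.int64)
        if self.gene_lengths is not None:
            self.gene_lengths = np.asarray(self.gene_lengths, dtype=float)
            if self.gene_lengths.shape != (len(self.gene_ids),):
                raise ValueError("gene_lengths length must equal gene count")
            if np.any(self.gene_lengths <= 0):
                raise ValueError("gene_lengths must be positive")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        lengths = None if self.gene_lengths is None else self.gene_lengths[keep]
        return CountMatrix(
            [self.gene_ids[i] for i in keep],
            list(self.sample_ids),
            self.counts[keep],
            lengths,
        )


@dataclass
class ConditionPartition:
    """The two sample groups of a tumor-vs-normal comparison."""

    tumor_samples: list[str]
    normal_samples: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.tumor_samples) & set(self.normal_samples)
        if overlap:
            raise ValueError(f"samples in both conditions: {sorted(overlap)[:5]}")

    @property
    def n_tumor(self) -> int:
        return len(self.tumor_samples)

    @property
    def n_normal(self) -> int:
        return len(self.normal_samples)


@dataclass
class GeneLabelTable:
    """Per-gene three-class labels: 0 = down-regulated, 1 = up-regulated, 2 = non-DEG."""

    gene_ids: list[str]
    labels: np.ndarray
    log2fc: np.ndarray
    padj: np.ndarray
    pvalue: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.log2fc = np.asarray(self.log2fc, dtype=float)
        self.padj = np.asarray(self.padj, dtype=float)
        if self.pvalue is not None:
            self.pvalue = np.asarray(self.pvalue, dtype=float)
        n = len(self.gene_ids)
        for arr, name in ((self.labels, "labels"), (self.log2fc, "log2fc"), (self.padj, "padj")):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per gene")
        if not set(np.unique(self.labels)) <= {0, 1, 2}:
            raise ValueError("labels must be in {0, 1, 2}")

    def to_frame(self) -> pd.DataFrame:
        pval = self.pvalue if self.pvalue is not None else np.full(len(self.gene_ids), np.nan)
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "log2FC": self.log2fc,
                "pvalue": pval,
                "padj": self.padj,
                "label": self.labels,
            }
        )

    def class_counts(self) -> dict[int, int]:
        return {c: int(np.sum(self.labels == c)) for c in (0, 1, 2)}


def _detect_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "," if ("," in header and "\t" not in header) else "\t"


def read_matrix(path: str | Path, kind: str = "expression") -> ExpressionMatrix | CountMatrix:
    """Read a gene × sample matrix from TSV/CSV.

    ``kind`` selects the container: ``"expression"`` (real-valued) or
    ``"counts"`` (non-negative integers).  Row and column order are
    preserved from the file.
    """
    if kind not in ("expression", "counts"):
        raise ValueError(f"kind must be 'expression' or 'counts', got {kind!r}")
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0,
                     float_precision="round_trip")
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate gene or sample ids")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        mask = bad.isna() & df[col].notna()
        if mask.any():
            row = df.index[mask.to_numpy().argmax()]
            raise ValueError(f"{path}: non-numeric value at gene {row!r}, sample {col!r}")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        g, s = np.argwhere(np.isnan(values))[0]
        raise ValueError(f"{path}: missing value at gene {df.index[g]!r}, sample {df.columns[s]!r}")
    genes = [str(g) for g in df.index]
    samples = [str(s) for s in df.columns]
    if kind == "counts":
        if np.any(values < 0):
            g, s = np.argwhere(values < 0)[0]
            raise ValueError(f"{path}: negative count at gene {genes[g]!r}, sample {samples[s]!r}")
        if not np.allclose(values, np.round(values)):
            g, s = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise ValueError(
                f"{path}: fractional count at gene {genes[g]!r}, sample {samples[s]!r}"
            )
        return CountMatrix(genes, samples, values)
    return ExpressionMatrix(genes, samples, values)


def write_matrix(matrix: ExpressionMatrix | CountMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a matrix container back to delimited text (bit-preserving round trip)."""
    df = matrix.to_frame()
    if isinstance(matrix, ExpressionMatrix):
        df.to_csv(path, sep=sep, index_label="gene_id", float_format="%.17g")
    else:
        df.to_csv(path, sep=sep, index_label="gene_id")


def partition_samples(
    sample_ids: Sequence[str], tumor_tag: str = "01A", normal_tag: str = "11A"
) -> ConditionPartition:
    """Split sample ids into tumor/normal groups by substring tags.

    Samples matching neither tag are excluded (TCGA matrices carry other
    specimen codes); a sample matching both tags is an error, as is an
    empty group.
    """
    if not tumor_tag or not normal_tag or tumor_tag == normal_tag:
        raise ValueError("tumor and normal tags must be non-empty and distinct")
    tumor, normal, dropped = [], [], []
    for sid in sample_ids:
        sid = str(sid)
        in_t, in_n = tumor_tag in sid, normal_tag in sid
        if in_t and in_n:
            raise ValueError(f"sample {sid!r} matches both condition tags")
        if in_t:
            tumor.append(sid)
        elif in_n:
            normal.append(sid)
        else:
            dropped.append(sid)
    if dropped:
        logger.info("partition_samples: excluded %d samples matching neither tag: %s",
                    len(dropped), dropped[:5])
    if not tumor:
        raise ValueError(f"no samples matched tumor tag {tumor_tag!r}")
    if not normal:
        raise ValueError(f"no samples matched normal tag {normal_tag!r}")
    return ConditionPartition(tumor, normal)


def write_labels(table: GeneLabelTable, path: str | Path, sep: str = "\t") -> None:
    table.to_frame().to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_labels(path: str | Path) -> GeneLabelTable:
    df = pd.read_csv(path, sep=_detect_sep(Path(path)))
    required = {"gene_id", "log2FC", "padj", "label"}
    if not required <= set(df.columns):
        raise ValueError(f"label table must have columns {sorted(required)}")
    pval = df["pvalue"].to_numpy() if "pvalue" in df.columns else None
    return GeneLabelTable(
        [str(g) for g in df["gene_id"]],
        df["label"].to_numpy(),
        df["log2FC"].to_numpy(),
        df["padj"].to_numpy(),
        pval,
    )
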