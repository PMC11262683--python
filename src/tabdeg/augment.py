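"""Condition-split feature augmentation.

Each gene's feature vector (its expression across samples) is split into
the tumor (T) and normal (N) sample blocks.  Per block, three families of
derived features are appended to the quantile-normalized raw block:

* principal-component scores from the eigendecomposition of the block's
  sample-sample covariance C = VDVᵀ;
* coordinates from a fuzzy k-NN-graph embedding fitted by minimizing the
  cross-entropy CE = Σ_e [w_h log(w_h/w_l) + (1−w_h) log((1−w_h)/(1−w_l))]
  between high- and low-dimensional edge weights;
* K-means cluster features (one-hot membership and centroid distances),
  with K chosen by the Calinski–Harabasz variance-ratio criterion
  VRC_K = (SSB/SSW) · (N−K)/(K−1).

The default budget (components = ceil(0.04·block width), 2 embedding
dimensions, K scanned over {2, 3}) adds 15–20% new columns on top of the
raw ones for cohorts with tens of samples per condition.

Fitting is split into ``fit`` (statistics from training genes only) and
``transform`` (projection of any genes), so cross-validation can stay
leakage-free; ``build_augmented_dataset`` fits and transforms on the full
gene set, which is the transductive behavior ``paper_mode`` reproduces.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import QuantileTransformer

from .config import AugmentConfig, PipelineConfig
from .io import ConditionPartition, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureBlock",
    "PCAModel",
    "EmbeddingModel",
    "KMeansModel",
    "AugmentedDataset",
    "split_blocks",
    "fit_transform_pca",
    "fit_transform_embedding",
    "kmeans_with_ch",
    "quantile_to_normal",
    "FeatureAugmenter",
    "build_augmented_dataset",
    "cross_entropy_edges",
]


@dataclass
class FeatureBlock:
    """One condition's columns of the expression matrix (genes × samples)."""

    gene_ids: list[str]
    condition: str  # "T" or "N"
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("block shape does not match id lists")


def split_blocks(
    expression: ExpressionMatrix, partition: ConditionPartition
) -> tuple[FeatureBlock, FeatureBlock]:
    """Split the expression matrix into the T and N sample blocks."""
    idx = {s: j for j, s in enumerate(expression.sample_ids)}
    t_idx = [idx[s] for s in partition.tumor_samples]
    n_idx = [idx[s] for s in partition.normal_samples]
    if not t_idx or not n_idx:
        raise ValueError("both condition blocks must be non-empty")
    g = list(expression.gene_ids)
    return (
        FeatureBlock(g, "T", list(partition.tumor_samples), expression.values[:, t_idx]),
        FeatureBlock(g, "N", list(partition.normal_samples), expression.values[:, n_idx]),
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    """Eigendecomposition of the block covariance C = VDVᵀ.

    Genes are the observations; the block's samples are the variables.
    ``u`` holds the per-column empirical means, ``eigenvalues`` are in
    non-increasing order and ``components`` (columns of V) are orthonormal.
    """

    u: np.ndarray
    components: np.ndarray  # (n_samples, p)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    p: int

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.u) @ self.components


def fit_transform_pca(block: FeatureBlock, p: int) -> tuple[PCAModel, np.ndarray]:
    """Project centered gene rows onto the top-p eigenvectors of C.

    The deviation matrix is B = X − h uᵀ (rows centered by the per-column
    means); C = BᵀB/(M−1) is eigendecomposed and eigenpairs are paired in
    decreasing eigenvalue order.  If ``p`` exceeds the covariance rank the
    request is truncated with a warning.
    """
    X = block.values
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 genes")
    if p < 1 or p > X.shape[1]:
        raise ValueError(f"p must be in [1, {X.shape[1]}]")
    u = X.mean(axis=0)
    B = X - u[None, :]
    C = (B.T @ B) / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int(np.sum(evals > max(evals[0], 0) * 1e-12)) if evals[0] > 0 else 0
    rank = max(rank, 1)
    if p > rank:
        warnings.warn(f"requested {p} components but covariance rank is {rank}; truncating")
        p = rank
    # fix sign for determinism: largest-magnitude loading positive
    for j in range(p):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    model = PCAModel(u=u, components=evecs[:, :p].copy(), eigenvalues=evals, p=p)
    return model, model.transform(X)


# ---------------------------------------------------------------------------
# Fuzzy-graph embedding
# ---------------------------------------------------------------------------


def _smooth_knn_weights(dist: np.ndarray, n_neighbors: int) -> np.ndarray:
    """Locally adaptive exponential kernel weights for each point's k-NN.

    Per point, the scale σ is calibrated by bisection so the effective
    neighbor count Σ_j exp(−max(0, d_j − ρ)/σ) equals log2(k), with ρ the
    distance to the nearest neighbor (weight 1 on that edge).
    """
    n, k = dist.shape
    target = np.log2(n_neighbors)
    rho = dist[:, 0]
    w = np.zeros_like(dist)
    for i in range(n):
        d = np.maximum(dist[i] - rho[i], 0.0)
        lo, hi = 1e-12, 1.0
        while np.exp(-d / hi).sum() < target and hi < 1e6:
            hi *= 2.0
        for _ in range(64):
            mid = 0.5 * (lo + hi)
            if np.exp(-d / mid).sum() > target:
                hi = mid
            else:
                lo = mid
        w[i] = np.exp(-d / (0.5 * (lo + hi)))
    return w


def cross_entropy_edges(w_h: np.ndarray, w_l: np.ndarray, eps: float = 1e-12) -> float:
    """Edge-wise fuzzy cross entropy Σ_e w_h log(w_h/w_l) + (1−w_h) log((1−w_h)/(1−w_l)).

    Zero iff w_l = w_h on every edge; the terms with w_h ∈ {0, 1} use the
    0·log 0 = 0 convention.
    """
    w_h = np.clip(np.asarray(w_h, dtype=float), 0.0, 1.0)
    w_l = np.clip(np.asarray(w_l, dtype=float), eps, 1.0 - eps)
    attract = np.where(w_h > 0, w_h * (np.log(np.maximum(w_h, eps)) - np.log(w_l)), 0.0)
    repel = np.where(
        w_h < 1, (1 - w_h) * (np.log(np.maximum(1 - w_h, eps)) - np.log(1 - w_l)), 0.0
    )
    return float(np.sum(attract + repel))


@dataclass
class EmbeddingModel:
    """Fitted fuzzy-graph embedding.

    Low-dimensional edge weights are w_l(e) = 1/(1 + ‖y_i − y_j‖²); the
    layout minimizes the cross entropy against the high-dimensional
    weights w_h over the symmetrized k-NN graph.
    """

    train_values: np.ndarray
    layout: np.ndarray
    edges: np.ndarray  # (n_edges, 2)
    w_h: np.ndarray
    n_neighbors: int
    ce_initial: float
    ce_final: float
    _nn: NearestNeighbors = field(repr=False, default=None)

    def low_dim_weight(self, d2: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + d2)

    def cross_entropy(self, layout: np.ndarray | None = None) -> float:
        y = self.layout if layout is None else layout
        d2 = np.sum((y[self.edges[:, 0]] - y[self.edges[:, 1]]) ** 2, axis=1)
        return cross_entropy_edges(self.w_h, self.low_dim_weight(d2))

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Embed new rows as the kernel-weighted mean of their training
        neighbors' layout coordinates (out-of-sample, leakage-free)."""
        values = np.atleast_2d(np.asarray(values, dtype=float))
        dist, idx = self._nn.kneighbors(values, n_neighbors=self.n_neighbors)
        w = _smooth_knn_weights(dist, self.n_neighbors)
        w = w / np.maximum(w.sum(axis=1, keepdims=True), 1e-12)
        return np.einsum("ij,ijk->ik", w, self.layout[idx])


def fit_transform_embedding(
    block_values: np.ndarray,
    d: int = 2,
    n_neighbors: int = 15,
    epochs: int = 100,
    seed: int = 0,
    negative_samples: int = 5,
    learning_rate: float = 1.0,
) -> tuple[EmbeddingModel, np.ndarray]:
    """Fit the fuzzy-graph embedding by SGD with negative sampling.

    Builds the k-NN graph, assigns high-dimensional weights with the
    locally adaptive kernel, symmetrizes directed weights a, b as
    a + b − ab, and descends the cross entropy from a random layout.  The
    returned layout is the best iterate seen, so its CE never exceeds the
    initial layout's.
    """
    X = np.asarray(block_values, dtype=float)
    n = X.shape[0]
    if d < 1:
        raise ValueError("embedding dimension must be >= 1")
    if n_neighbors >= n:
        raise ValueError(f"n_neighbors ({n_neighbors}) must be < number of genes ({n})")
    rng = np.random.default_rng(seed)

    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    w = _smooth_knn_weights(dist, n_neighbors)

    rows = np.repeat(np.arange(n), n_neighbors)
    directed = coo_matrix((w.ravel(), (rows, idx.ravel())), shape=(n, n)).tocsr()
    prod = directed.multiply(directed.T)
    sym = (directed + directed.T - prod).tocoo()
    mask = sym.row < sym.col
    edges = np.column_stack([sym.row[mask], sym.col[mask]])
    w_h = np.asarray(sym.data[mask], dtype=float)

    y = rng.normal(scale=10.0, size=(n, d))  # spread init: repulsion stays gentle
    model = EmbeddingModel(X, y, edges, w_h, n_neighbors, 0.0, 0.0, _nn=nn)
    ce_init = model.cross_entropy(y)
    best_y, best_ce = y.copy(), ce_init

    i_idx, j_idx = edges[:, 0], edges[:, 1]
    for epoch in range(epochs):
        lr = learning_rate * (1.0 - epoch / epochs)
        # attractive forces along graph edges, scaled by w_h
        diff = y[i_idx] - y[j_idx]
        d2 = np.sum(diff**2, axis=1)
        grad = (2.0 * w_h / (1.0 + d2))[:, None] * diff
        grad = np.clip(grad, -4.0, 4.0)
        np.subtract.at(y, i_idx, lr * grad)
        np.add.at(y, j_idx, lr * grad)
        # repulsive forces against sampled non-neighbors (w_h treated as 0)
        for _ in range(negative_samples):
            k_idx = rng.integers(0, n, size=edges.shape[0])
            diff = y[i_idx] - y[k_idx]
            d2 = np.sum(diff**2, axis=1)
            rep = (2.0 / ((d2 + 1e-3) * (1.0 + d2)))[:, None] * diff
            rep = np.clip(rep, -4.0, 4.0)
            np.add.at(y, i_idx, lr * rep)
        ce = model.cross_entropy(y)
        if ce < best_ce:
            best_ce, best_y = ce, y.copy()

    model.layout = best_y
    model.ce_initial = ce_init
    model.ce_final = best_ce
    logger.debug("embedding: CE %.4f -> %.4f over %d epochs", ce_init, best_ce, epochs)
    return model, best_y.copy()


# ---------------------------------------------------------------------------
# K-means with Calinski–Harabasz K selection
# ---------------------------------------------------------------------------


def variance_ratio(values: np.ndarray, assignments: np.ndarray) -> tuple[float, float, float]:
    """(SSB, SSW, VRC) of a clustering.

    SSB = Σ_i n_i‖m_i − m‖², SSW = Σ_i Σ_{x∈C_i} ‖x − m_i‖², and
    VRC = (SSB/SSW) · (N−K)/(K−1); SSW = 0 yields VRC = +∞ and SSB = 0
    yields 0.
    """
    X = np.asarray(values, dtype=float)
    labels = np.asarray(assignments)
    ks = np.unique(labels)
    m = X.mean(axis=0)
    ssb = ssw = 0.0
    for k in ks:
        pts = X[labels == k]
        mk = pts.mean(axis=0)
        ssb += len(pts) * float(np.sum((mk - m) ** 2))
        ssw += float(np.sum((pts - mk) ** 2))
    K, N = len(ks), len(X)
    if ssb == 0.0:
        return ssb, ssw, 0.0
    if ssw == 0.0:
        return ssb, ssw, np.inf
    return ssb, ssw, (ssb / ssw) * (N - K) / (K - 1)


@dataclass
class KMeansModel:
    """K-means clustering with the VRC scan that selected K."""

    k: int
    centroids: np.ndarray
    global_centroid: np.ndarray
    cluster_sizes: np.ndarray
    assignments: np.ndarray
    ssb: float
    ssw: float
    vrc_by_k: dict[int, float]
    onehot: bool = True
    distance: bool = True

    def transform(self, values: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(values, dtype=float))
        dists = np.linalg.norm(X[:, None, :] - self.centroids[None, :, :], axis=2)
        cols = []
        if self.onehot:
            cols.append(np.eye(self.k)[np.argmin(dists, axis=1)])
        if self.distance:
            cols.append(dists)
        return np.hstack(cols)

    @property
    def n_feature_columns(self) -> int:
        return self.k * (int(self.onehot) + int(self.distance))


def kmeans_with_ch(
    block_values: np.ndarray,
    k_range: tuple[int, int] = (2, 3),
    seed: int = 0,
    onehot: bool = True,
    distance: bool = True,
) -> tuple[KMeansModel, np.ndarray]:
    """Lloyd's algorithm (k-means++ init) for each K in range; keep the K
    maximizing the variance-ratio criterion, ties resolved toward smaller K.

    Cluster features are one-hot membership (K columns) and/or Euclidean
    distance to each centroid (K columns).
    """
    X = np.asarray(block_values, dtype=float)
    k_lo, k_hi = k_range
    if k_lo < 2 or k_hi >= len(X):
        raise ValueError(f"K range must lie in [2, {len(X) - 1}]")
    best = None
    vrc_by_k: dict[int, float] = {}
    for k in range(k_lo, k_hi + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        ssb, ssw, vrc = variance_ratio(X, km.labels_)
        vrc_by_k[k] = vrc
        if best is None or vrc > best[0]:  # strict > keeps ties at smaller K
            best = (vrc, k, km, ssb, ssw)
    _, k, km, ssb, ssw = best
    sizes = np.bincount(km.labels_, minlength=k)
    model = KMeansModel(
        k=k,
        centroids=km.cluster_centers_.copy(),
        global_centroid=X.mean(axis=0),
        cluster_sizes=sizes,
        assignments=km.labels_.copy(),
        ssb=ssb,
        ssw=ssw,
        vrc_by_k=vrc_by_k,
        onehot=onehot,
        distance=distance,
    )
    return model, model.transform(X)


# ---------------------------------------------------------------------------
# Quantile-to-normal transform
# ---------------------------------------------------------------------------


def quantile_to_normal(
    block_values: np.ndarray, n_quantiles: int | None = None
) -> tuple[np.ndarray, QuantileTransformer]:
    """Map each column onto a standard-normal field via its empirical CDF.

    Parameter-free and rank-based: monotone on distinct values, the
    empirical median maps to ≈0, and outputs are clipped to finite bounds.
    Returns the transformed block and the fitted monotone map (which also
    transforms unseen rows and inverts on the training values up to ties).
    """
    X = np.asarray(block_values, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("quantile transform needs >= 10 rows per column")
    nq = n_quantiles or min(1000, X.shape[0])
    qt = QuantileTransformer(
        output_distribution="normal", n_quantiles=nq, subsample=max(X.shape[0], 10**6),
        random_state=0
    )
    return qt.fit_transform(X), qt


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


@dataclass
class AugmentedDataset:
    """The experimental feature table E: quantile-normalized raw T and N
    blocks followed by the per-block derived features, with per-column
    provenance labels (raw-T, pca-N, umap-T, cluster-N, …)."""

    gene_ids: list[str]
    values: np.ndarray
    feature_names: list[str]
    provenance: list[str]
    n_raw: int
    n_augmented: int

    @property
    def boost_ratio(self) -> float:
        return self.n_augmented / self.n_raw

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.feature_names)

    def provenance_frame(self):
        import pandas as pd

        return pd.DataFrame({"feature": self.feature_names, "origin": self.provenance})

    def subset_genes(self, rows: np.ndarray) -> "AugmentedDataset":
        rows = np.asarray(rows)
        return AugmentedDataset(
            [self.gene_ids[i] for i in rows],
            self.values[rows],
            list(self.feature_names),
            list(self.provenance),
            self.n_raw,
            self.n_augmented,
        )


class FeatureAugmenter:
    """Fits all per-block augmentation statistics on one gene set and
    projects any gene set through them.

    ``fit`` on training genes + ``transform`` on held-out genes gives the
    leakage-free mode used by cross-validation; ``fit`` and ``transform``
    on the same full gene set reproduces the transductive behavior.
    """

    def __init__(self, config: AugmentConfig | None = None, seed: int = 0) -> None:
        self.config = config or AugmentConfig()
        self.config.validate()
        self.seed = seed
        self._fitted = False

    def fit(self, block_t: np.ndarray, block_n: np.ndarray) -> "FeatureAugmenter":
        cfg = self.config
        self._models = {}
        for tag, block in (("T", np.asarray(block_t, float)), ("N", np.asarray(block_n, float))):
            p = max(1, int(np.ceil(cfg.pca_fraction * block.shape[1])))
            _, qt = quantile_to_normal(block)
            pca, _ = fit_transform_pca(
                FeatureBlock([str(i) for i in range(len(block))], tag,
                             [f"{tag}{j}" for j in range(block.shape[1])], block),
                p,
            )
            emb, _ = fit_transform_embedding(
                block,
                d=cfg.embed_dim,
                n_neighbors=min(cfg.n_neighbors, len(block) - 1),
                epochs=cfg.embed_epochs,
                seed=self.seed,
                negative_samples=cfg.negative_samples,
            )
            km, _ = kmeans_with_ch(
                block,
                (cfg.k_min, cfg.k_max),
                seed=self.seed,
                onehot=cfg.cluster_onehot,
                distance=cfg.cluster_distance,
            )
            self._models[tag] = {"qt": qt, "pca": pca, "embed": emb, "kmeans": km}
        self._fitted = True
        return self

    def transform(
        self, block_t: np.ndarray, block_n: np.ndarray, gene_ids: list[str],
        t_samples: list[str] | None = None, n_samples: list[str] | None = None,
    ) -> AugmentedDataset:
        if not self._fitted:
            raise RuntimeError("FeatureAugmenter must be fitted before transform")
        blocks = {"T": np.asarray(block_t, float), "N": np.asarray(block_n, float)}
        cols, names, prov = [], [], []

        def stage(tag: str, what: str, fn):
            try:
                return fn()
            except Exception as exc:  # pragma: no cover - error path
                raise RuntimeError(f"augmentation stage {what}({tag}) failed: {exc}") from exc

        for tag in ("T", "N"):
            m = self._models[tag]
            raw = stage(tag, "quantile", lambda: m["qt"].transform(blocks[tag]))
            sample_names = (t_samples if tag == "T" else n_samples) or [
                f"{tag}{j}" for j in range(raw.shape[1])
            ]
            cols.append(raw)
            names += [f"raw-{tag}:{s}" for s in sample_names]
            prov += [f"raw-{tag}"] * raw.shape[1]
        for tag in ("T", "N"):
            m = self._models[tag]
            pca = stage(tag, "pca", lambda: m["pca"].transform(blocks[tag]))
            cols.append(pca)
            names += [f"pca-{tag}:{j + 1}" for j in range(pca.shape[1])]
            prov += [f"pca-{tag}"] * pca.shape[1]
        for tag in ("T", "N"):
            m = self._models[tag]
            emb = stage(tag, "embed", lambda: m["embed"].transform(blocks[tag]))
            cols.append(emb)
            names += [f"umap-{tag}:{j + 1}" for j in range(emb.shape[1])]
            prov += [f"umap-{tag}"] * emb.shape[1]
        for tag in ("T", "N"):
            m = self._models[tag]
            clu = stage(tag, "kmeans", lambda: m["kmeans"].transform(blocks[tag]))
            cols.append(clu)
            km = m["kmeans"]
            sub = []
            if km.onehot:
                sub += [f"cluster-{tag}:in{j + 1}" for j in range(km.k)]
            if km.distance:
                sub += [f"cluster-{tag}:dist{j + 1}" for j in range(km.k)]
            names += sub
            prov += [f"cluster-{tag}"] * clu.shape[1]

        n_raw = blocks["T"].shape[1] + blocks["N"].shape[1]
        values = np.hstack(cols)
        return AugmentedDataset(
            list(gene_ids), values, names, prov, n_raw, values.shape[1] - n_raw
        )


def build_augmented_dataset(
    expression: ExpressionMatrix,
    partition: ConditionPartition,
    config: PipelineConfig | AugmentConfig | None = None,
    seed: int | None = None,
) -> AugmentedDataset:
    """Fit and apply the augmentation on the full gene set (transductive).

    For leakage-free cross-validation use :class:`FeatureAugmenter`
    directly, fitting on training genes only.
    """
    if isinstance(config, PipelineConfig):
        aug_cfg = config.augment
        seed = config.seed if seed is None else seed
    else:
        aug_cfg = config or AugmentConfig()
        seed = 0 if seed is None else seed
    bt, bn = split_blocks(expression, partition)
    aug = FeatureAugmenter(aug_cfg, seed=seed).fit(bt.values, bn.values)
    out = aug.transform(bt.values, bn.values, list(expression.gene_ids),
                        bt.sample_ids, bn.sample_ids)
    logger.info(
        "augmentation: %d raw + %d new columns (boost %.1f%%)",
        out.n_raw, out.n_augmented, 100 * out.boost_ratio,
    )
    return out
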