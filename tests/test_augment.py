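import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist

from tabdeg import SimulationConfig, simulate_counts
from tabdeg.augment import (
    FeatureAugmenter,
    FeatureBlock,
    build_augmented_dataset,
    cross_entropy_edges,
    fit_transform_embedding,
    fit_transform_pca,
    kmeans_with_ch,
    quantile_to_normal,
    split_blocks,
    variance_ratio,
)
from tabdeg.config import AugmentConfig


def _block(values, tag="T"):
    values = np.asarray(values, dtype=float)
    return FeatureBlock(
        [f"g{i}" for i in range(values.shape[0])], tag,
        [f"s{j}" for j in range(values.shape[1])], values,
    )


class TestPCA:
    def test_rank_one_line_recovers_diagonal_direction(self):
        t = np.linspace(-3, 3, 25)
        model, scores = fit_transform_pca(_block(np.column_stack([t, t])), p=2)
        v = model.components[:, 0]
        assert np.abs(v @ np.array([1, 1]) / np.sqrt(2)) == pytest.approx(1.0, abs=1e-12)
        assert model.eigenvalues[1] == pytest.approx(0.0, abs=1e-12)

    def test_eigenvalues_sum_to_covariance_trace(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 8)) * rng.uniform(0.5, 4, size=8)
        model, scores = fit_transform_pca(_block(X), p=3)
        C = np.cov(X, rowvar=False)
        assert model.eigenvalues.sum() == pytest.approx(np.trace(C), rel=1e-10)
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-10)

    def test_constant_column_contributes_nothing(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([rng.normal(size=40), np.full(40, 2.5)])
        model, scores = fit_transform_pca(_block(X), p=1)
        assert abs(model.components[1, 0]) < 1e-10

    def test_full_p_projection_is_isometric(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 6))
        _, scores = fit_transform_pca(_block(X), p=6)
        np.testing.assert_allclose(pdist(scores), pdist(X), rtol=1e-9)

    def test_p_beyond_rank_warns_and_truncates(self):
        t = np.linspace(0, 1, 20)
        with pytest.warns(UserWarning, match="rank"):
            model, scores = fit_transform_pca(_block(np.column_stack([t, 2 * t])), p=2)
        assert scores.shape[1] == 1


class TestEmbedding:
    def test_printed_cross_entropy_values(self):
        # single edge, w_h = 1, w_l = 0.5 contributes log 2
        assert cross_entropy_edges([1.0], [0.5]) == pytest.approx(np.log(2), abs=1e-9)
        assert cross_entropy_edges([1.0], [0.5]) == pytest.approx(0.6931, abs=1e-4)
        # zero point: w_l = w_h
        w = np.array([0.2, 0.7, 1.0])
        assert cross_entropy_edges(w, w) == pytest.approx(0.0, abs=1e-6)
        assert cross_entropy_edges([0.3, 0.9], [0.6, 0.2]) > 0

    def test_ce_never_worse_than_initial_layout(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 4))
        model, _ = fit_transform_embedding(X, n_neighbors=8, epochs=40, seed=1)
        assert model.ce_final <= model.ce_initial
        assert model.ce_final < model.ce_initial  # actually improved

    def test_separated_clusters_stay_separated_in_layout(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(80, 5))
        b = rng.normal(size=(80, 5)) + 10  # between-distance ~10x within
        model, Y = fit_transform_embedding(np.vstack([a, b]), n_neighbors=10,
                                           epochs=150, seed=0)
        between = cdist(Y[:80], Y[80:]).mean()
        within = 0.5 * (cdist(Y[:80], Y[:80]).mean() + cdist(Y[80:], Y[80:]).mean())
        assert between > within

    def test_out_of_sample_rows_land_near_their_cluster(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(60, 5))
        b = rng.normal(size=(60, 5)) + 10
        model, Y = fit_transform_embedding(np.vstack([a, b]), n_neighbors=8,
                                           epochs=100, seed=0)
        new = model.transform(rng.normal(size=(10, 5)) + 10)
        d_b = np.linalg.norm(new - Y[60:].mean(axis=0), axis=1)
        d_a = np.linalg.norm(new - Y[:60].mean(axis=0), axis=1)
        assert np.all(d_b < d_a)

    def test_too_few_genes_for_neighbors_errors(self):
        with pytest.raises(ValueError, match="n_neighbors"):
            fit_transform_embedding(np.zeros((5, 3)), n_neighbors=10)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 4))
        _, y1 = fit_transform_embedding(X, n_neighbors=6, epochs=20, seed=3)
        _, y2 = fit_transform_embedding(X, n_neighbors=6, epochs=20, seed=3)
        np.testing.assert_array_equal(y1, y2)


def _brute_force_vrc(X, labels):
    """Independent VRC computation from pairwise definitions."""
    X = np.asarray(X, dtype=float)
    m = X.mean(axis=0)
    ks = np.unique(labels)
    ssb = sum(np.sum(labels == k) * np.sum((X[labels == k].mean(axis=0) - m) ** 2)
              for k in ks)
    ssw = sum(np.sum((X[labels == k] - X[labels == k].mean(axis=0)) ** 2) for k in ks)
    K, N = len(ks), len(X)
    if ssb == 0:
        return 0.0
    if ssw == 0:
        return np.inf
    return (ssb / ssw) * (N - K) / (K - 1)


class TestKMeansVRC:
    def test_worked_example_vrc_200(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        ssb, ssw, vrc = variance_ratio(X, np.array([0, 0, 1, 1]))
        assert (ssb, ssw, vrc) == (100.0, 1.0, 200.0)
        model, feats = kmeans_with_ch(X, (2, 2), seed=0)
        assert model.vrc_by_k[2] == pytest.approx(200.0)
        assert sorted(model.cluster_sizes.tolist()) == [2, 2]

    def test_identical_points_give_zero_vrc(self):
        X = np.ones((6, 2))
        assert variance_ratio(X, np.array([0, 0, 0, 1, 1, 1]))[2] == 0.0

    def test_vrc_matches_brute_force_on_random_clusterings(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            n = rng.integers(4, 13)
            k = rng.integers(2, 5)
            X = rng.normal(size=(n, rng.integers(1, 4)))
            labels = rng.integers(0, k, size=n)
            if len(np.unique(labels)) < 2:
                continue
            ours = variance_ratio(X, labels)[2]
            ref = _brute_force_vrc(X, labels)
            if np.isinf(ref):
                assert np.isinf(ours)
            else:
                assert ours == pytest.approx(ref, rel=1e-10)

    def test_vrc_matches_sklearn_on_kmeans_assignments(self):
        from sklearn.metrics import calinski_harabasz_score

        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(size=(20, 3)), rng.normal(size=(20, 3)) + 4])
        model, _ = kmeans_with_ch(X, (2, 4), seed=0)
        for k, vrc in model.vrc_by_k.items():
            km_labels = __import__("sklearn.cluster", fromlist=["KMeans"]).KMeans(
                n_clusters=k, n_init=10, random_state=0).fit_predict(X)
            assert variance_ratio(X, km_labels)[2] == pytest.approx(
                calinski_harabasz_score(X, km_labels), rel=1e-9)

    def test_near_degenerate_scan_has_well_defined_winner(self):
        X = np.arange(10, dtype=float).reshape(-1, 1)
        model, _ = kmeans_with_ch(X, (2, 9), seed=0)
        assert model.k in model.vrc_by_k
        finite = {k: v for k, v in model.vrc_by_k.items() if np.isfinite(v)}
        if np.isfinite(model.vrc_by_k[model.k]):
            assert model.vrc_by_k[model.k] == max(finite.values())

    def test_cluster_features_are_onehot_plus_distances(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        model, feats = kmeans_with_ch(X, (2, 2), seed=0)
        assert feats.shape == (4, 4)
        np.testing.assert_allclose(feats[:, :2].sum(axis=1), 1.0)
        assert np.all(feats[:, 2:] >= 0)


class TestQuantileTransform:
    def test_median_maps_near_zero(self):
        rng = np.random.default_rng(10)
        X = rng.exponential(size=(501, 1))
        Z, qt = quantile_to_normal(X)
        med_row = np.argsort(X[:, 0])[len(X) // 2]
        assert abs(Z[med_row, 0]) < 0.02

    def test_monotone_on_distinct_values(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(100, 1)) ** 3
        Z, _ = quantile_to_normal(X)
        order = np.argsort(X[:, 0])
        assert np.all(np.diff(Z[order, 0]) >= 0)

    def test_exponential_column_becomes_standard_normal(self):
        rng = np.random.default_rng(12)
        X = rng.exponential(size=(1000, 1))
        Z, _ = quantile_to_normal(X)
        assert abs(Z.mean()) < 0.05
        assert abs(Z.std() - 1.0) < 0.1

    def test_invertible_on_training_values(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(200, 2))
        Z, qt = quantile_to_normal(X)
        np.testing.assert_allclose(qt.inverse_transform(Z), X, atol=1e-6)

    def test_too_few_rows_errors(self):
        with pytest.raises(ValueError, match="10 rows"):
            quantile_to_normal(np.zeros((5, 2)))


class TestAugmentedDataset:
    def test_boost_band_with_default_hyperparameters(self):
        ds = simulate_counts(SimulationConfig(n_genes=300, n_tumor=50, n_normal=50,
                                              seed=20))
        aug = build_augmented_dataset(ds.expression, ds.condition, seed=0)
        assert aug.n_raw == 100
        assert 0.15 <= aug.boost_ratio <= 0.20
        assert len(aug.gene_ids) == 300  # row conservation
        assert len(aug.feature_names) == aug.n_raw + aug.n_augmented
        assert len(set(aug.provenance)) == 8  # raw/pca/umap/cluster x T/N

    def test_transform_is_row_equivariant(self, small_dataset):
        bt, bn = split_blocks(small_dataset.expression, small_dataset.condition)
        cfg = AugmentConfig(embed_epochs=20)
        aug = FeatureAugmenter(cfg, seed=0).fit(bt.values[:300], bn.values[:300])
        rows = np.arange(300, 360)
        out = aug.transform(bt.values[rows], bn.values[rows], [f"g{i}" for i in rows])
        perm = np.random.default_rng(0).permutation(len(rows))
        out_p = aug.transform(bt.values[rows][perm], bn.values[rows][perm],
                              [f"g{i}" for i in rows[perm]])
        np.testing.assert_allclose(out_p.values, out.values[perm], atol=1e-10)

    def test_fit_transform_deterministic_given_seed(self, small_dataset):
        bt, bn = split_blocks(small_dataset.expression, small_dataset.condition)
        cfg = AugmentConfig(embed_epochs=15)
        a = FeatureAugmenter(cfg, seed=5).fit(bt.values, bn.values)
        b = FeatureAugmenter(cfg, seed=5).fit(bt.values, bn.values)
        va = a.transform(bt.values, bn.values, small_dataset.expression.gene_ids).values
        vb = b.transform(bt.values, bn.values, small_dataset.expression.gene_ids).values
        np.testing.assert_array_equal(va, vb)
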