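import numpy as np
import pytest

from tabdeg._autodiff import Tensor
from tabdeg.config import TabNetConfig
from tabdeg.tabnet import (
    TabNetClassifier,
    _GhostBatchNorm,
    label_smoothing_loss,
    predict_and_importance,
    pretrain_masked,
)


class TestLabelSmoothingLoss:
    def test_zero_epsilon_is_plain_cross_entropy(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(8, 3))
        y = rng.integers(0, 3, 8)
        loss = float(label_smoothing_loss(Tensor(logits), y, 0.0).data)
        p = np.exp(logits - logits.max(1, keepdims=True))
        p /= p.sum(1, keepdims=True)
        expected = -np.log(p[np.arange(8), y]).mean()
        assert loss == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("eps", [0.0, 0.1, 0.5])
    def test_uniform_logits_cost_is_log3_for_any_epsilon(self, eps):
        loss = float(label_smoothing_loss(Tensor(np.zeros((4, 3))),
                                          np.array([0, 1, 2, 0]), eps).data)
        assert loss == pytest.approx(np.log(3), rel=1e-12)

    def test_optimum_is_the_smoothed_target_not_onehot(self):
        # minimize over logits for one sample; softmax at the optimum must
        # equal the smoothed target distribution
        eps = 0.3
        y = np.array([1])
        z = Tensor(np.zeros((1, 3)))
        for _ in range(3000):
            z.grad = None
            loss = label_smoothing_loss(z, y, eps)
            loss.backward()
            z.data -= 0.5 * z.grad
        p = np.exp(z.data)
        p /= p.sum()
        target = np.array([eps / 3, 1 - eps + eps / 3, eps / 3])
        np.testing.assert_allclose(p[0], target, atol=1e-4)
        assert p[0, 1] < 1.0  # not one-hot

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            label_smoothing_loss(Tensor(np.zeros((1, 3))), np.array([3]), 0.1)


@pytest.fixture(scope="module")
def built():
    clf = TabNetClassifier(TabNetConfig(), seed=0)
    clf._build(12)
    return clf


class TestEncoderPieces:
    def test_feature_transform_width_is_nd_plus_na(self, built):
        d, a = built.feature_transform(np.random.default_rng(0).normal(size=(4, 12)))
        assert d.shape == (4, 8) and a.shape == (4, 8)

    def test_identical_rows_get_identical_outputs_in_eval(self, built):
        x = np.random.default_rng(1).normal(size=12)
        d, a = built.feature_transform(np.vstack([x, x]))
        np.testing.assert_array_equal(d[0], d[1])

    def test_ghost_bn_with_full_virtual_batch_is_plain_bn(self):
        params = {}
        bn = _GhostBatchNorm(5, virtual_batch_size=64, momentum=0.1, name="t",
                             params=params)
        X = np.random.default_rng(2).normal(size=(64, 5)) * 3 + 1
        out = bn(Tensor(X), training=True).data
        expected = (X - X.mean(0)) / np.sqrt(X.var(0) + 1e-5)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_attentive_step_uniform_mask_and_prior_update(self):
        cfg = TabNetConfig(mask_type="sparsemax")
        clf = TabNetClassifier(cfg, seed=0)
        clf._build(10)
        # zero attention weights -> zero logits -> uniform sparsemax mask
        clf.att_W[0].data[:] = 0.0
        clf.att_b[0].data[:] = 0.0
        a = np.random.default_rng(3).normal(size=(4, 8))
        mask, priors = clf.attentive_step(a, np.ones((4, 10)))
        np.testing.assert_allclose(mask, 0.1, atol=1e-12)
        # P' = P * (gamma - M) = 1.3 - 1/F elementwise
        np.testing.assert_allclose(priors, 1.3 - 0.1, atol=1e-12)

    def test_negative_priors_rejected(self):
        clf = TabNetClassifier(TabNetConfig(), seed=0)
        clf._build(6)
        with pytest.raises(ValueError, match="non-negative"):
            clf.attentive_step(np.zeros((1, 8)), -np.ones((1, 6)))

    def test_gradients_match_finite_differences(self):
        cfg = TabNetConfig(batch_size=16, virtual_batch_size=8, lambda_sparse=1e-3)
        clf = TabNetClassifier(cfg, seed=0)
        clf._build(6)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(16, 6))
        y = rng.integers(0, 3, 16)

        def loss_value():
            out = clf._forward(X, training=True)
            return label_smoothing_loss(out["logits"], y, 0.1) + out["sparsity"]

        for p in clf.params.values():
            p.grad = None
        loss_value().backward()
        eps = 1e-6
        for key in ("shared.W", "att0.W", "head.W", "dep_step0.bn.gamma"):
            t = clf.params[key]
            analytic = t.grad.copy()
            flat = t.data.ravel()
            for idx in (0, flat.size // 2):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = float(loss_value().data)
                flat[idx] = orig - eps
                down = float(loss_value().data)
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert numeric == pytest.approx(analytic.ravel()[idx],
                                                rel=1e-4, abs=1e-7), key


class TestTraining:
    def test_learns_separable_problem(self, trained_toy):
        clf, X, y = trained_toy
        assert clf.history[-1]["train_loss"] < clf.history[0]["train_loss"]
        assert (clf.predict(X) == y).mean() >= 0.95

    def test_probabilities_and_masks_are_normalized(self, trained_toy):
        clf, X, y = trained_toy
        proba = clf.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        for mask in clf.masks(X):
            np.testing.assert_allclose(mask.sum(axis=1), 1.0, atol=1e-6)
            assert np.all(mask >= 0)

    def test_constant_feature_gets_negligible_importance(self, trained_toy):
        clf, X, y = trained_toy
        imp = clf.feature_importances(X)
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(imp >= 0)
        assert imp[10] < 1.0 / (2 * X.shape[1])  # the constant column

    def test_sparsity_term_is_exactly_zero_when_lambda_is_zero(self, separable_toy):
        X, y = separable_toy
        clf = TabNetClassifier(TabNetConfig(lambda_sparse=0.0), seed=1)
        clf.fit(X, y, max_epochs=3)
        assert all(h["sparsity_loss"] == 0.0 for h in clf.history)

    def test_identical_seed_gives_identical_trajectories(self, separable_toy):
        X, y = separable_toy
        runs = []
        for _ in range(2):
            clf = TabNetClassifier(TabNetConfig(), seed=7)
            clf.fit(X[:240], y[:240], X[240:], y[240:], max_epochs=8)
            runs.append([h["val_logloss"] for h in clf.history])
        assert runs[0] == runs[1]

    def test_missing_training_class_rejected(self, separable_toy):
        X, y = separable_toy
        keep = y != 1
        clf = TabNetClassifier(TabNetConfig(), seed=0)
        with pytest.raises(ValueError, match="missing classes"):
            clf.fit(X[keep], y[keep])

    def test_feature_width_mismatch_rejected(self, trained_toy):
        clf, X, y = trained_toy
        with pytest.raises(ValueError, match="width"):
            clf.predict_proba(X[:, :5])

    def test_predict_and_importance_wrapper(self, trained_toy):
        clf, X, y = trained_toy
        proba, labels, imp = predict_and_importance(clf, X[:20])
        assert set(np.unique(labels)) <= {0, 1, 2}
        np.testing.assert_array_equal(labels, proba.argmax(axis=1))
        assert imp.sum() == pytest.approx(1.0)

    def test_importance_equivariant_under_feature_permutation(self, separable_toy):
        X, y = separable_toy
        cfg = TabNetConfig()
        clf = TabNetClassifier(cfg, seed=3)
        clf.fit(X, y, max_epochs=5)
        imp = clf.feature_importances(X)

        perm = np.random.default_rng(4).permutation(X.shape[1])
        inv = np.argsort(perm)
        state = clf.state_dict()
        # rewire the input side of the network to match the permuted columns
        for key in ("input_bn.gamma", "input_bn.beta", "input_bn.running_mean",
                    "input_bn.running_var", "att0.b"):
            state[key] = state[key][perm]
        for key in ("att0.bn.gamma", "att0.bn.beta", "att0.bn.running_mean",
                    "att0.bn.running_var"):
            state[key] = state[key][perm]
        state["shared.W"] = state["shared.W"][perm, :]
        state["att0.W"] = state["att0.W"][:, perm]
        clf2 = TabNetClassifier(cfg, seed=3)
        clf2._build(X.shape[1])
        clf2.load_state(state)
        imp2 = clf2.feature_importances(X[:, perm])
        np.testing.assert_allclose(imp2, imp[perm], atol=1e-10)


class TestPretraining:
    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError, match="ratio"):
            pretrain_masked(np.zeros((10, 4)), 1.5)

    def test_reconstruction_error_decreases(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(300, 8))
        X[:, 0] = 2 * X[:, 1] + 0.1 * rng.normal(size=300)  # reconstructable structure
        cfg = TabNetConfig(batch_size=128, virtual_batch_size=64)
        _, mse = pretrain_masked(X, 0.3, cfg, seed=0, epochs=8)
        assert mse[-1] < mse[0]

    def test_warm_start_trains_successfully(self, separable_toy):
        X, y = separable_toy
        cfg = TabNetConfig()
        state, _ = pretrain_masked(X, 0.2, cfg, seed=0, epochs=3)
        clf = TabNetClassifier(cfg, seed=0)
        clf.fit(X, y, max_epochs=5, init_from=state)
        assert clf.history[-1]["train_loss"] < np.log(3)
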