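"""Sparse-attention tabular classifier (numpy implementation).

The encoder follows the attentive tabular architecture: an input batch
norm, a feature transformer built from GLU blocks (one shared across all
uses plus one step-specific block, residual-connected with scale √0.5 and
ghost batch normalization over virtual batches), and per decision step an
attentive transformer producing a sparse feature-selection mask via
sparsemax or 1.5-entmax.  Masks are multiplied by "priors" — per-feature
multipliers starting at one and updated as P' = P ⊙ (γ − M) so features
used at one step are discounted at the next.  Decision outputs pass
through ReLU, are summed over steps, and feed a linear softmax head
trained with label smoothing.  Aggregating the masks, weighted by each
step's total positive decision output, yields a global feature-importance
vector.

Defaults reproduce the published training schedule: n_d = n_a = 8, one
decision step, entmax masks, λ_sparse = 0, batch 512 with virtual batches
of 64, Adam at 2e-2 with ×0.95 decay at epochs 50/100/150, early stopping
on validation log-loss with patience 50 capped at 200 epochs.  An
optional masked-feature pretraining pass (per-feature Bernoulli masking,
feature-transformer decoder) yields encoder weights to warm-start the
classifier.  Everything runs on the CPU in float64 and is deterministic
given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, concat
from .config import TabNetConfig
from .sparse_activations import entmax15_t, sparsemax_t

logger = logging.getLogger(__name__)

__all__ = [
    "TabNetClassifier",
    "TrainedModel",
    "label_smoothing_loss",
    "pretrain_masked",
    "predict_and_importance",
]

_SQRT_HALF = float(np.sqrt(0.5))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class _GhostBatchNorm:
    """Batch normalization over fixed-size virtual sub-batches.

    With ``virtual_batch_size >= batch size`` this is plain batch norm.
    Running statistics (momentum-averaged over virtual batches) are used
    in evaluation mode.
    """

    def __init__(self, dim: int, virtual_batch_size: int, momentum: float, name: str,
                 params: dict):
        self.dim = dim
        self.vbs = virtual_batch_size
        self.momentum = momentum
        self.eps = 1e-5
        self.gamma = Tensor(np.ones(dim))
        self.beta = Tensor(np.zeros(dim))
        params[f"{name}.gamma"] = self.gamma
        params[f"{name}.beta"] = self.beta
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if not training:
            xhat = (x - self.running_mean) * (1.0 / np.sqrt(self.running_var + self.eps))
            return self.gamma * xhat + self.beta
        n = x.shape[0]
        chunks = []
        for start in range(0, n, self.vbs):
            c = x[slice(start, min(start + self.vbs, n))]
            m = c.mean(axis=0, keepdims=True)
            v = ((c - m) ** 2.0).mean(axis=0, keepdims=True)
            chunks.append((c - m) * ((v + self.eps) ** -0.5))
            self.running_mean = (1 - self.momentum) * self.running_mean \
                + self.momentum * m.data[0]
            self.running_var = (1 - self.momentum) * self.running_var \
                + self.momentum * v.data[0]
        xhat = chunks[0] if len(chunks) == 1 else concat(chunks, axis=0)
        return self.gamma * xhat + self.beta


class _GLUBlock:
    """affine → ghost batch norm → gated linear unit.

    The affine weights may be shared across several blocks (the shared
    layers of the feature transformer); the batch norm and its running
    statistics are always private to the block, since each use sees a
    different input distribution.
    """

    def __init__(self, in_dim: int, units: int, vbs: int, momentum: float, name: str,
                 params: dict, rng: np.random.Generator,
                 shared_fc: tuple[Tensor, Tensor] | None = None):
        if shared_fc is not None:
            self.W, self.b = shared_fc
        else:
            self.W = Tensor(_glorot(rng, in_dim, 2 * units))
            self.b = Tensor(np.zeros(2 * units))
            params[f"{name}.W"] = self.W
            params[f"{name}.b"] = self.b
        self.bn = _GhostBatchNorm(2 * units, vbs, momentum, f"{name}.bn", params)
        self.units = units

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        h = self.bn(x @ self.W + self.b, training)
        return h[:, : self.units] * h[:, self.units :].sigmoid()


class _FeatureTransformer:
    """Shared GLU block followed by a step-specific GLU block with a
    √0.5-scaled residual connection."""

    def __init__(self, shared: _GLUBlock, step_block: _GLUBlock):
        self.shared = shared
        self.step_block = step_block

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        h = self.shared(x, training)
        return (self.step_block(h, training) + h) * _SQRT_HALF


@dataclass
class TrainedModel:
    """Fitted classifier state: the network, its configuration, the
    training history, and the aggregated feature-importance vector."""

    classifier: "TabNetClassifier"
    config: TabNetConfig
    history: list[dict]
    feature_importance: np.ndarray
    feature_names: list[str] | None = None

    def importance_frame(self):
        import pandas as pd

        names = self.feature_names or [f"f{i}" for i in range(len(self.feature_importance))]
        return pd.DataFrame({"feature": names, "importance": self.feature_importance})


def label_smoothing_loss(logits: Tensor, labels: np.ndarray, epsilon: float,
                         n_classes: int = 3) -> Tensor:
    """Cross entropy against (1−ε) on the true class plus ε/C everywhere.

    ε = 0 recovers the standard cross entropy; the loss is the batch mean.
    """
    if not 0 <= epsilon < 1:
        raise ValueError("label smoothing epsilon must be in [0, 1)")
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(f"labels must be in [0, {n_classes - 1}]")
    targets = np.full((len(labels), n_classes), epsilon / n_classes)
    targets[np.arange(len(labels)), labels] += 1.0 - epsilon
    shift = logits.data.max(axis=1, keepdims=True)  # detached max for stability
    logp = logits - shift - ((logits - shift).exp().sum(axis=1, keepdims=True)).log()
    return -(Tensor(targets) * logp).sum(axis=1).mean()


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def _log_loss(proba: np.ndarray, y: np.ndarray, smoothing: float = 0.0,
              n_classes: int = 3) -> float:
    p = np.clip(proba, 1e-15, 1.0)
    targets = np.full((len(y), n_classes), smoothing / n_classes)
    targets[np.arange(len(y)), y] += 1.0 - smoothing
    return float(-(targets * np.log(p)).sum(axis=1).mean())


class _Adam:
    def __init__(self, params: dict[str, Tensor], lr: float, weight_decay: float):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, lr: float) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    @staticmethod
    def zero_grad(params: dict[str, Tensor]) -> None:
        for p in params.values():
            p.grad = None


class TabNetClassifier:
    """The attentive tabular three-class classifier.

    scikit-learn-style surface: :meth:`fit`, :meth:`predict`,
    :meth:`predict_proba`, plus :meth:`feature_importances` (aggregated
    masks) and the building-block methods :meth:`feature_transform` and
    :meth:`attentive_step` exposing the encoder internals.
    """

    def __init__(self, config: TabNetConfig | None = None, seed: int = 0):
        self.config = config or TabNetConfig()
        self.config.validate()
        self.seed = seed
        self._built_for: int | None = None

    # -- construction -----------------------------------------------------

    def _build(self, n_features: int) -> None:
        cfg = self.config
        rng = np.random.default_rng(self.seed)
        self.params: dict[str, Tensor] = {}
        units = cfg.n_d + cfg.n_a
        vbs, mom = cfg.virtual_batch_size, cfg.momentum
        self.input_bn = _GhostBatchNorm(n_features, 10**9, mom, "input_bn", self.params)
        shared_W = Tensor(_glorot(rng, n_features, 2 * units))
        shared_b = Tensor(np.zeros(2 * units))
        self.params["shared.W"], self.params["shared.b"] = shared_W, shared_b
        self.ft_initial = _FeatureTransformer(
            _GLUBlock(n_features, units, vbs, mom, "shared_init", self.params, rng,
                      shared_fc=(shared_W, shared_b)),
            _GLUBlock(units, units, vbs, mom, "dep_init", self.params, rng),
        )
        self.ft_steps = [
            _FeatureTransformer(
                _GLUBlock(n_features, units, vbs, mom, f"shared_step{i}", self.params, rng,
                          shared_fc=(shared_W, shared_b)),
                _GLUBlock(units, units, vbs, mom, f"dep_step{i}", self.params, rng),
            )
            for i in range(cfg.n_steps)
        ]
        self.att_W = [Tensor(_glorot(rng, cfg.n_a, n_features)) for _ in range(cfg.n_steps)]
        self.att_b = [Tensor(np.zeros(n_features)) for _ in range(cfg.n_steps)]
        self.att_bn = []
        for i in range(cfg.n_steps):
            self.params[f"att{i}.W"] = self.att_W[i]
            self.params[f"att{i}.b"] = self.att_b[i]
            self.att_bn.append(_GhostBatchNorm(n_features, vbs, mom, f"att{i}.bn", self.params))
        self.head_W = Tensor(_glorot(rng, cfg.n_d, cfg.n_classes))
        self.head_b = Tensor(np.zeros(cfg.n_classes))
        self.params["head.W"] = self.head_W
        self.params["head.b"] = self.head_b
        self._mask_fn = sparsemax_t if cfg.mask_type == "sparsemax" else entmax15_t
        self._built_for = n_features

    def _check_width(self, X: np.ndarray) -> None:
        if self._built_for is None:
            raise RuntimeError("model has not been fitted or built")
        if X.shape[1] != self._built_for:
            raise ValueError(
                f"feature width {X.shape[1]} does not match the trained width {self._built_for}"
            )

    # -- encoder building blocks ------------------------------------------

    def feature_transform(self, x: np.ndarray, training: bool = False
                          ) -> tuple[np.ndarray, np.ndarray]:
        """Initial feature transformer split into (n_d, n_a) activations."""
        self._check_width(np.atleast_2d(x))
        out = self.ft_initial(Tensor(np.atleast_2d(x)), training)
        return out.data[:, : self.config.n_d], out.data[:, self.config.n_d :]

    def attentive_step(self, a: np.ndarray, priors: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
        """One attentive-transformer application: M = mask(BN(aW + b) ⊙ P),
        P' = P ⊙ (γ − M).  Evaluation-mode batch norm."""
        a_t = Tensor(np.atleast_2d(a))
        priors = np.atleast_2d(np.asarray(priors, dtype=float))
        if np.any(priors < 0):
            raise ValueError("priors must be non-negative")
        logits = self.att_bn[0](a_t @ self.att_W[0] + self.att_b[0], False)
        mask = self._mask_fn(logits * Tensor(priors))
        return mask.data, priors * (self.config.gamma - mask.data)

    # -- forward ----------------------------------------------------------

    def _forward(self, X: np.ndarray, training: bool) -> dict:
        cfg = self.config
        x = self.input_bn(Tensor(X), training)
        out = self.ft_initial(x, training)
        a = out[:, slice(cfg.n_d, cfg.n_d + cfg.n_a)]
        priors = Tensor(np.ones((X.shape[0], self._built_for)))
        decision_sum = None
        masks, step_d = [], []
        entropy_terms = []
        for i in range(cfg.n_steps):
            logits = self.att_bn[i](a @ self.att_W[i] + self.att_b[i], training)
            mask = self._mask_fn(logits * priors)
            masks.append(mask)
            priors = priors * (cfg.gamma - mask)
            entropy_terms.append((mask * ((mask + 1e-15).log())).sum(axis=1).mean())
            h = self.ft_steps[i](x * mask, training)
            d = h[:, slice(0, cfg.n_d)].relu()
            step_d.append(d)
            decision_sum = d if decision_sum is None else decision_sum + d
            a = h[:, slice(cfg.n_d, cfg.n_d + cfg.n_a)]
        logits = decision_sum @ self.head_W + self.head_b
        sparsity = None
        if cfg.lambda_sparse > 0:
            total = entropy_terms[0]
            for t in entropy_terms[1:]:
                total = total + t
            sparsity = total * (-cfg.lambda_sparse / cfg.n_steps)
        return {
            "logits": logits,
            "masks": masks,
            "step_d": step_d,
            "decision": decision_sum,
            "sparsity": sparsity,
        }

    # -- training ---------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        max_epochs: int | None = None,
        init_from: dict[str, np.ndarray] | None = None,
    ) -> "TabNetClassifier":
        """Train with Adam, milestone LR decay, and early stopping on
        validation log-loss (patience from the config).  ``init_from``
        warm-starts matching parameters (e.g. from masked pretraining)."""
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=np.int64)
        present = set(np.unique(y))
        if present != set(range(cfg.n_classes)):
            missing = sorted(set(range(cfg.n_classes)) - present)
            raise ValueError(f"training labels missing classes {missing}")
        self._build(X.shape[1])
        if init_from is not None:
            self.load_state(init_from, strict=False)
        rng = np.random.default_rng(self.seed + 1)
        opt = _Adam(self.params, cfg.learning_rate, cfg.weight_decay)
        n_epochs = max_epochs if max_epochs is not None else cfg.max_epochs
        use_val = X_val is not None and y_val is not None

        best_loss, best_state, best_epoch, wait = np.inf, None, -1, 0
        self.history: list[dict] = []
        for epoch in range(n_epochs):
            lr = cfg.learning_rate * cfg.lr_decay ** sum(
                epoch >= m for m in cfg.milestones
            )
            order = rng.permutation(len(X))
            epoch_loss, epoch_sparse, n_batches = 0.0, 0.0, 0
            for start in range(0, len(X), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                out = self._forward(X[idx], training=True)
                loss = label_smoothing_loss(
                    out["logits"], y[idx], cfg.label_smoothing, cfg.n_classes
                )
                if out["sparsity"] is not None:
                    loss = loss + out["sparsity"]
                    epoch_sparse += float(out["sparsity"].data)
                opt.zero_grad(self.params)
                loss.backward()
                opt.step(lr)
                epoch_loss += float(loss.data)
                n_batches += 1
            record = {
                "epoch": epoch,
                "lr": lr,
                "train_loss": epoch_loss / n_batches,
                "sparsity_loss": epoch_sparse / n_batches,
            }
            if use_val:
                proba = self.predict_proba(X_val)
                record["val_logloss"] = _log_loss(proba, np.asarray(y_val))
                record["val_smoothed_logloss"] = _log_loss(
                    proba, np.asarray(y_val), cfg.label_smoothing, cfg.n_classes
                )
                monitored = record["val_logloss"]
            else:
                monitored = record["train_loss"]
            self.history.append(record)
            if monitored < best_loss - 1e-12:
                best_loss, best_epoch, wait = monitored, epoch, 0
                best_state = self.state_dict()
            else:
                wait += 1
                if wait >= cfg.patience:
                    logger.info("early stopping at epoch %d (best %d)", epoch, best_epoch)
                    break
        if best_state is not None:
            self.load_state(best_state)
        self.best_epoch = best_epoch
        self.stopped_epoch = self.history[-1]["epoch"]
        return self

    # -- inference --------------------------------------------------------

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self._check_width(X)
        return _softmax(self._forward(X, training=False)["logits"].data)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def masks(self, X: np.ndarray) -> list[np.ndarray]:
        """Per-step attention masks in evaluation mode (rows sum to one)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self._check_width(X)
        return [m.data for m in self._forward(X, training=False)["masks"]]

    def feature_importances(self, X: np.ndarray) -> np.ndarray:
        """Global importance: per-step masks weighted by each row's total
        positive decision output at that step, summed over steps and rows,
        normalized to sum to one."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self._check_width(X)
        out = self._forward(X, training=False)
        agg = np.zeros(X.shape[1])
        for mask, d in zip(out["masks"], out["step_d"]):
            eta = d.data.sum(axis=1)
            agg += (eta[:, None] * mask.data).sum(axis=0)
        total = agg.sum()
        return agg / total if total > 0 else np.full(X.shape[1], 1.0 / X.shape[1])

    # -- state ------------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: t.data.copy() for k, t in self.params.items()}
        for name, bn in self._named_bns():
            state[f"{name}.running_mean"] = bn.running_mean.copy()
            state[f"{name}.running_var"] = bn.running_var.copy()
        return state

    def load_state(self, state: dict[str, np.ndarray], strict: bool = True) -> None:
        for k, t in self.params.items():
            if k in state:
                t.data = state[k].copy()
            elif strict:
                raise KeyError(f"missing parameter {k}")
        for name, bn in self._named_bns():
            if f"{name}.running_mean" in state:
                bn.running_mean = state[f"{name}.running_mean"].copy()
                bn.running_var = state[f"{name}.running_var"].copy()

    def _named_bns(self):
        yield "input_bn", self.input_bn
        yield "shared_init.bn", self.ft_initial.shared.bn
        yield "dep_init.bn", self.ft_initial.step_block.bn
        for i, ft in enumerate(self.ft_steps):
            yield f"shared_step{i}.bn", ft.shared.bn
            yield f"dep_step{i}.bn", ft.step_block.bn
        for i, bn in enumerate(self.att_bn):
            yield f"att{i}.bn", bn


def predict_and_importance(model: TabNetClassifier | TrainedModel, X: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Class probabilities, hard labels in {0, 1, 2}, and the aggregated
    feature-importance vector for the given rows."""
    clf = model.classifier if isinstance(model, TrainedModel) else model
    proba = clf.predict_proba(X)
    return proba, np.argmax(proba, axis=1), clf.feature_importances(X)


def pretrain_masked(
    X: np.ndarray,
    pretraining_ratio: float,
    config: TabNetConfig | None = None,
    seed: int = 0,
    epochs: int = 20,
) -> tuple[dict[str, np.ndarray], list[float]]:
    """Self-supervised masked-feature pretraining.

    Each cell is masked with an independent Bernoulli(ratio) draw; the
    encoder sees the unmasked remainder and a feature-transformer decoder
    reconstructs the masked cells (MSE on masked cells of column-
    standardized values).  Returns encoder weights suitable for
    ``fit(init_from=...)`` and the per-epoch masked-cell MSE trajectory.
    """
    if not 0 < pretraining_ratio < 1:
        raise ValueError("pretraining_ratio must be in (0, 1)")
    cfg = config or TabNetConfig()
    X = np.asarray(X, dtype=float)
    mu, sd = X.mean(axis=0), np.maximum(X.std(axis=0), 1e-8)
    Xs = (X - mu) / sd

    clf = TabNetClassifier(cfg, seed=seed)
    clf._build(X.shape[1])
    rng = np.random.default_rng(seed + 2)
    dec_rng = np.random.default_rng(seed + 3)
    units = cfg.n_d
    dec_params: dict[str, Tensor] = {}
    dec_glu = _GLUBlock(units, units, cfg.virtual_batch_size, cfg.momentum, "dec.glu",
                        dec_params, dec_rng)
    dec_W = Tensor(_glorot(dec_rng, units, X.shape[1]))
    dec_b = Tensor(np.zeros(X.shape[1]))
    dec_params["dec.W"], dec_params["dec.b"] = dec_W, dec_b
    all_params = {**clf.params, **dec_params}
    opt = _Adam(all_params, cfg.learning_rate, cfg.weight_decay)

    mse_history: list[float] = []
    for epoch in range(epochs):
        order = rng.permutation(len(Xs))
        total_se, total_cells = 0.0, 0.0
        for start in range(0, len(Xs), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = Xs[idx]
            mask = rng.random(batch.shape) < pretraining_ratio
            out = clf._forward(batch * (~mask), training=True)
            recon = dec_glu(out["decision"], True) @ dec_W + dec_b
            diff = (recon - Tensor(batch)) * Tensor(mask.astype(float))
            n_masked = max(mask.sum(), 1)
            loss = (diff**2.0).sum() * (1.0 / n_masked)
            opt.zero_grad(all_params)
            loss.backward()
            opt.step(cfg.learning_rate)
            total_se += float(loss.data) * n_masked
            total_cells += n_masked
        mse_history.append(total_se / max(total_cells, 1))
    logger.info("pretraining: masked-cell MSE %.4f -> %.4f", mse_history[0], mse_history[-1])
    return clf.state_dict(), mse_history
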