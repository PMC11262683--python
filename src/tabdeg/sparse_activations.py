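"""Sparse probability transforms for attention masks.

``sparsemax`` is the Euclidean projection onto the probability simplex
(sorted-threshold algorithm); ``entmax15`` is the 1.5-entmax transform,
interpolating between softmax and sparsemax.  Both operate row-wise,
return rows summing to one, and may zero out coordinates.  Analytic
Jacobians back the autodiff wrappers used inside the network.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, custom_op

__all__ = [
    "sparsemax",
    "entmax15",
    "sparsemax_t",
    "entmax15_t",
    "entmax15_bisect",
]


def _as_2d(z: np.ndarray) -> tuple[np.ndarray, bool]:
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        return z[None, :], True
    return z, False


def sparsemax(z: np.ndarray) -> np.ndarray:
    """Row-wise Euclidean projection of z onto the simplex.

    With z sorted in decreasing order, the support size is the largest k
    with 1 + k·z_(k) > Σ_{j<=k} z_(j); the threshold is
    τ = (Σ_{j<=k} z_(j) − 1)/k and p = max(z − τ, 0).
    """
    z, squeeze = _as_2d(z)
    if not np.all(np.isfinite(z)):
        raise ValueError("sparsemax requires finite input")
    srt = np.sort(z, axis=1)[:, ::-1]
    csum = np.cumsum(srt, axis=1)
    ks = np.arange(1, z.shape[1] + 1)
    support = 1.0 + ks * srt > csum
    k = support.sum(axis=1)
    tau = (csum[np.arange(len(z)), k - 1] - 1.0) / k
    p = np.maximum(z - tau[:, None], 0.0)
    return p[0] if squeeze else p


def _sparsemax_vjp(p: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """J = diag(1_S) − 1_S 1_Sᵀ / |S| on the support S."""
    supp = p > 0
    gsum = (grad * supp).sum(axis=-1, keepdims=True)
    nsupp = supp.sum(axis=-1, keepdims=True)
    return np.where(supp, grad - gsum / nsupp, 0.0)


def entmax15(z: np.ndarray) -> np.ndarray:
    """Row-wise exact 1.5-entmax: p_i = max(0, z_i/2 − τ)² with Σ p = 1.

    The threshold is found in closed form from cumulative moments of the
    sorted halved scores (for each candidate support size k,
    τ_k = mean_k − sqrt(max(0, 1/k − var_k)); the valid k is the largest
    with τ_k <= z_(k)/2).
    """
    z, squeeze = _as_2d(z)
    if not np.all(np.isfinite(z)):
        raise ValueError("entmax15 requires finite input")
    u = np.sort(z / 2.0, axis=1)[:, ::-1]
    ks = np.arange(1, z.shape[1] + 1)
    mean = np.cumsum(u, axis=1) / ks
    meansq = np.cumsum(u**2, axis=1) / ks
    var = meansq - mean**2
    delta = np.maximum((1.0 - ks * var) / ks, 0.0)
    tau = mean - np.sqrt(delta)
    support = tau <= u
    k = support.sum(axis=1)
    tau_star = tau[np.arange(len(z)), k - 1]
    p = np.maximum(z / 2.0 - tau_star[:, None], 0.0) ** 2
    # guard against round-off: renormalize exactly
    p /= p.sum(axis=1, keepdims=True)
    return p[0] if squeeze else p


def _entmax15_vjp(p: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """J = diag(s) − s sᵀ / Σs with s = √p on the support."""
    s = np.sqrt(p)
    gs = grad * s
    ratio = gs.sum(axis=-1, keepdims=True) / np.maximum(s.sum(axis=-1, keepdims=True), 1e-300)
    return gs - s * ratio


def entmax15_bisect(z: np.ndarray, n_iter: int = 60) -> np.ndarray:
    """Reference 1.5-entmax via bisection on τ (Σ max(0, z/2 − τ)² = 1)."""
    z, squeeze = _as_2d(z)
    u = z / 2.0
    lo = u.max(axis=1) - 1.0
    hi = u.max(axis=1)
    for _ in range(n_iter):
        tau = 0.5 * (lo + hi)
        total = np.sum(np.maximum(u - tau[:, None], 0.0) ** 2, axis=1)
        lo = np.where(total > 1.0, tau, lo)
        hi = np.where(total > 1.0, hi, tau)
    tau = 0.5 * (lo + hi)
    p = np.maximum(u - tau[:, None], 0.0) ** 2
    p /= p.sum(axis=1, keepdims=True)
    return p[0] if squeeze else p


def sparsemax_t(z: Tensor) -> Tensor:
    return custom_op(z, sparsemax, _sparsemax_vjp)


def entmax15_t(z: Tensor) -> Tensor:
    return custom_op(z, entmax15, _entmax15_vjp)
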