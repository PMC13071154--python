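"""Minimal NumPy neural-network primitives used across the package.

Implements exactly what the window classifier and the ensemble combiners
need: same-padded 1-D convolution, ReLU, masked max-pooling, dense layers,
softmax cross-entropy and an Adam optimizer — each with an explicit backward
pass.  All randomness goes through explicitly passed ``numpy`` generators, so
identical seeds give identical parameters and identical training histories in
single-threaded mode.
"""

from __future__ import annotations

import numpy as np


def conv1d_forward(
    x: np.ndarray, w: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Same-padded 1-D convolution.

    x: (B, Cin, W); w: (Cout, Cin, k); b: (Cout,).  Returns (out, cols) where
    cols is the im2col tensor cached for the backward pass.
    """
    cout, cin, k = w.shape
    B, _, W = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
    cols = np.empty((B, cin, k, W))
    for j in range(k):
        cols[:, :, j, :] = xp[:, :, j : j + W]
    cols2 = cols.reshape(B, cin * k, W)
    out = np.einsum("oc,bcw->bow", w.reshape(cout, cin * k), cols2) + b[None, :, None]
    return out, cols2


def conv1d_backward(
    dout: np.ndarray, cols: np.ndarray, w: np.ndarray, in_width: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of conv1d_forward w.r.t. input, weights and bias."""
    cout, cin, k = w.shape
    B, _, W = dout.shape
    dw = np.einsum("bow,bcw->oc", dout, cols).reshape(cout, cin, k)
    db = dout.sum(axis=(0, 2))
    dcols = np.einsum("oc,bow->bcw", w.reshape(cout, cin * k), dout)
    dcols = dcols.reshape(B, cin, k, W)
    p = k // 2
    dxp = np.zeros((B, cin, in_width + 2 * p))
    for j in range(k):
        dxp[:, :, j : j + W] += dcols[:, :, j, :]
    return (dxp[:, :, p : p + in_width] if p else dxp), dw, db


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_backward(dout: np.ndarray, x: np.ndarray) -> np.ndarray:
    return dout * (x > 0)


def masked_max_pool(
    h: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Max over the window axis, ignoring padded columns.

    h: (B, F, W); mask: (B, W) with 1 on real columns.  Padded columns are set
    to -inf before the max so they can never win.
    """
    neg = np.where(mask[:, None, :] > 0, h, -np.inf)
    idx = neg.argmax(axis=2)
    out = np.take_along_axis(neg, idx[:, :, None], axis=2)[:, :, 0]
    return out, idx


def masked_max_pool_backward(
    dout: np.ndarray, idx: np.ndarray, shape: tuple[int, ...]
) -> np.ndarray:
    dh = np.zeros(shape)
    np.put_along_axis(dh, idx[:, :, None], dout[:, :, None], axis=2)
    return dh


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(p[np.arange(n), y] + 1e-300).mean())
    g = p.copy()
    g[np.arange(n), y] -= 1.0
    return loss, g / n


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Adam:
    """Adaptive-moment gradient descent over a dict of named parameters."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class EarlyStopping:
    """Patience-based stopper tracking the best dev metric and its snapshot.

    ``update`` is called once per epoch with the dev metric and a parameter
    snapshot; it returns True when ``patience`` consecutive epochs have failed
    to improve on the best metric seen (lower is better).
    """

    def __init__(self, patience: int) -> None:
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_metric = np.inf
        self.best_epoch = 0
        self.best_snapshot: dict[str, np.ndarray] | None = None
        self._since_best = 0

    def update(
        self, epoch: int, metric: float, snapshot: dict[str, np.ndarray]
    ) -> bool:
        if metric < self.best_metric:
            self.best_metric = metric
            self.best_epoch = epoch
            self.best_snapshot = {k: v.copy() for k, v in snapshot.items()}
            self._since_best = 0
        else:
            self._since_best += 1
        return self._since_best >= self.patience
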