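"""Minimal NumPy layers with explicit forward/backward passes.

Convolution is implemented via im2col. Each ``forward`` returns the output
plus a cache consumed by ``backward``; parameter gradients accumulate in
``grads`` so weight-shared (recurrent) applications sum their contributions
across iterations.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

__all__ = ["Conv2d", "ChannelNorm", "relu", "relu_backward", "Linear",
           "global_avg_pool", "global_avg_pool_backward", "softmax_cross_entropy"]


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    hp, wp = h + 2 * pad, w + 2 * pad
    xp = np.zeros((n, c, hp, wp), dtype=x.dtype)
    xp[:, :, pad:pad + h, pad:pad + w] = x
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    s0, s1, s2, s3 = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, (n, c, kh, kw, oh, ow),
        (s0, s1, s2, s3, s2 * stride, s3 * stride), writeable=False)
    return np.ascontiguousarray(cols.reshape(n, c * kh * kw, oh * ow)), (oh, ow, xp.shape)


def _col2im(cols: np.ndarray, xp_shape, kh, kw, stride, pad, h, w):
    n, c, hp, wp = xp_shape
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    xp = np.zeros(xp_shape, dtype=cols.dtype)
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += cols[:, :, i, j]
    return xp[:, :, pad:pad + h, pad:pad + w]


class Conv2d:
    def __init__(self, in_ch: int, out_ch: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator = None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k * k
        self.params: Dict[str, np.ndarray] = {
            "W": rng.standard_normal((out_ch, in_ch, k, k)) * np.sqrt(2.0 / fan_in),
            "b": np.zeros(out_ch),
        }
        self.grads: Dict[str, np.ndarray] = {k_: np.zeros_like(v)
                                             for k_, v in self.params.items()}
        self.k, self.stride, self.pad = k, stride, k // 2
        self.in_ch, self.out_ch = in_ch, out_ch

    def forward(self, x: np.ndarray) -> Tuple[np.ndarray, tuple]:
        n = x.shape[0]
        cols, (oh, ow, xp_shape) = _im2col(x, self.k, self.k, self.stride, self.pad)
        wmat = self.params["W"].reshape(self.out_ch, -1)
        out = (wmat @ cols).reshape(n, self.out_ch, oh, ow)
        out += self.params["b"][None, :, None, None]
        return out, (cols, xp_shape, x.shape)

    def backward(self, grad: np.ndarray, cache) -> np.ndarray:
        cols, xp_shape, x_shape = cache
        n, _, oh, ow = grad.shape
        gmat = grad.reshape(n, self.out_ch, oh * ow)
        wmat = self.params["W"].reshape(self.out_ch, -1)
        self.grads["W"] += np.einsum("nop,ncp->oc", gmat, cols).reshape(self.params["W"].shape)
        self.grads["b"] += grad.sum(axis=(0, 2, 3))
        gcols = np.einsum("oc,nop->ncp", wmat, gmat)
        return _col2im(gcols, xp_shape, self.k, self.k, self.stride, self.pad,
                       x_shape[2], x_shape[3])


class ChannelNorm:
    """Per-sample normalization over (channels, space) with per-channel affine.

    Statistics are computed from the current sample only (no batch or
    running statistics), so folded and unfolded evaluations are exactly
    equivalent and inference is deterministic. Normalizing across channels
    as well as space keeps the statistics well defined even on 1x1 feature
    maps.
    """

    def __init__(self, n_ch: int, eps: float = 1e-5):
        self.params = {"gamma": np.ones(n_ch), "beta": np.zeros(n_ch)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.eps = eps

    def forward(self, x: np.ndarray) -> Tuple[np.ndarray, tuple]:
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        out = xhat * self.params["gamma"][None, :, None, None] \
            + self.params["beta"][None, :, None, None]
        return out, (xhat, inv)

    def backward(self, grad: np.ndarray, cache) -> np.ndarray:
        xhat, inv = cache
        g = self.params["gamma"][None, :, None, None]
        self.grads["gamma"] += (grad * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += grad.sum(axis=(0, 2, 3))
        gx = grad * g
        return inv * (gx - gx.mean(axis=(1, 2, 3), keepdims=True)
                      - xhat * (gx * xhat).mean(axis=(1, 2, 3), keepdims=True))


def relu(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    mask = x > 0
    return x * mask, mask


def relu_backward(grad: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return grad * mask


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator = None):
        rng = rng or np.random.default_rng(0)
        self.params = {
            "W": rng.standard_normal((n_in, n_out)) * np.sqrt(1.0 / n_in),
            "b": np.zeros(n_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        return x @ self.params["W"] + self.params["b"], x

    def backward(self, grad: np.ndarray, x: np.ndarray) -> np.ndarray:
        self.grads["W"] += x.T @ grad
        self.grads["b"] += grad.sum(axis=0)
        return grad @ self.params["W"].T


def global_avg_pool(x: np.ndarray) -> Tuple[np.ndarray, tuple]:
    return x.mean(axis=(2, 3)), x.shape


def global_avg_pool_backward(grad: np.ndarray, shape) -> np.ndarray:
    n, c, h, w = shape
    return np.broadcast_to(grad[:, :, None, None], shape) / (h * w)


def softmax_cross_entropy(scores: np.ndarray, labels: np.ndarray
                          ) -> Tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient wrt scores."""
    z = scores - scores.max(axis=1, keepdims=True)
    expz = np.exp(z)
    probs = expz / expz.sum(axis=1, keepdims=True)
    n = scores.shape[0]
    loss = -np.log(probs[np.arange(n), labels] + 1e-12).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n
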