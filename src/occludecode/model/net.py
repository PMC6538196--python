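"""Folded recurrent network: shared-weight residual iterations per unit.

Each unit applies an input transform (strided conv + channel norm + ReLU)
followed by ``n_iterations`` applications of the recurrence
``h <- h + K(h)``, where ``K`` = conv + channel norm + ReLU re-uses the same
weights at every iteration. Readout stage 0 is the purely feedforward pass.
``unfold`` materializes the equivalent explicit deep network with tied
blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .._rng import child_rng
from ..errors import ConfigurationError
from .layers import (
    ChannelNorm,
    Conv2d,
    Linear,
    global_avg_pool,
    global_avg_pool_backward,
    relu,
    relu_backward,
)

__all__ = ["ArchSettings", "RecurrentUnit", "FoldedNet", "build_net", "forward",
           "forward_backward", "unfold", "UnfoldedNet"]


@dataclass(frozen=True)
class ArchSettings:
    """Toy scale: 64x64 inputs, ~50k parameters, CPU-trainable in minutes."""

    channels: Tuple[int, ...] = (8, 16, 16, 32, 32)
    kernel: int = 3
    input_size: int = 64
    n_classes: int = 4

    def __post_init__(self) -> None:
        if len(self.channels) == 0:
            raise ConfigurationError("need at least one layer")


class RecurrentUnit:
    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        self.conv_in = Conv2d(in_ch, out_ch, k, stride=2, rng=rng)
        self.norm_in = ChannelNorm(out_ch)
        self.conv_res = Conv2d(out_ch, out_ch, k, stride=1, rng=rng)
        self.norm_res = ChannelNorm(out_ch)

    # -- input transform ---------------------------------------------------
    def input_forward(self, x):
        h, c1 = self.conv_in.forward(x)
        h, c2 = self.norm_in.forward(h)
        h, c3 = relu(h)
        return h, (c1, c2, c3)

    def input_backward(self, grad, cache):
        c1, c2, c3 = cache
        grad = relu_backward(grad, c3)
        grad = self.norm_in.backward(grad, c2)
        return self.conv_in.backward(grad, c1)

    # -- one residual iteration (shared weights) ---------------------------
    def k_forward(self, h):
        z, c1 = self.conv_res.forward(h)
        z, c2 = self.norm_res.forward(z)
        z, c3 = relu(z)
        return z, (c1, c2, c3)

    def k_backward(self, grad, cache):
        c1, c2, c3 = cache
        grad = relu_backward(grad, c3)
        grad = self.norm_res.backward(grad, c2)
        return self.conv_res.backward(grad, c1)

    @property
    def layers(self):
        return (self.conv_in, self.norm_in, self.conv_res, self.norm_res)


class FoldedNet:
    """Hierarchy of recurrent units plus a linear readout head."""

    def __init__(self, arch: ArchSettings, seed: int):
        self.arch = arch
        self.seed = int(seed)
        rng = child_rng(seed, 40)
        self.units: List[RecurrentUnit] = []
        in_ch = 1
        for out_ch in arch.channels:
            self.units.append(RecurrentUnit(in_ch, out_ch, arch.kernel, rng))
            in_ch = out_ch
        self.head = Linear(arch.channels[-1], arch.n_classes, rng=rng)

    @property
    def n_units(self) -> int:
        return len(self.units)

    def parameters(self):
        for u in self.units:
            for layer in u.layers:
                for name, p in layer.params.items():
                    yield layer, name, p
        for name, p in self.head.params.items():
            yield self.head, name, p

    def n_parameters(self) -> int:
        return sum(p.size for _, _, p in self.parameters())

    def zero_grads(self) -> None:
        for u in self.units:
            for layer in u.layers:
                for k in layer.grads:
                    layer.grads[k][:] = 0.0
        for k in self.head.grads:
            self.head.grads[k][:] = 0.0


def build_net(arch: ArchSettings = ArchSettings(), seed: int = 0) -> FoldedNet:
    """Deterministically initialized folded net; weights within a unit are
    shared across recurrent iterations by construction (the parameter count
    is independent of the iteration budget)."""
    return FoldedNet(arch, seed)


def _check_stage(stage: int) -> int:
    stage = int(stage)
    if stage < 0:
        raise ConfigurationError("readout stage must be non-negative")
    return stage


def forward(net: FoldedNet, images: np.ndarray, stage: int = 0,
            ) -> Tuple[np.ndarray, np.ndarray]:
    """Run images (n, h, w) or (n, 1, h, w) through the net at a readout
    stage (= recurrent iterations per unit). Returns (penultimate_features,
    class_scores)."""
    feats, scores, _ = forward_backward(net, images, stage, labels=None)
    return feats, scores


def forward_backward(net: FoldedNet, images: np.ndarray, stage: int,
                     labels: np.ndarray = None):
    """Forward pass, optionally followed by backpropagation through the
    shared-weight iterations (gradients accumulate across iterations)."""
    stage = _check_stage(stage)
    x = np.asarray(images, dtype=float)
    if x.ndim == 3:
        x = x[:, None]

    unit_caches = []
    h = x
    for u in net.units:
        h, in_cache = u.input_forward(h)
        iter_caches = []
        for _ in range(stage):
            z, kc = u.k_forward(h)
            h = h + z
            iter_caches.append(kc)
        unit_caches.append((in_cache, iter_caches))
    feats, gap_shape = global_avg_pool(h)
    scores, lin_cache = net.head.forward(feats)

    if labels is None:
        return feats, scores, None

    from .layers import softmax_cross_entropy

    loss, gscores = softmax_cross_entropy(scores, labels)
    grad = net.head.backward(gscores, lin_cache)
    grad = global_avg_pool_backward(grad, gap_shape)
    for u, (in_cache, iter_caches) in zip(reversed(net.units),
                                          reversed(unit_caches)):
        for kc in reversed(iter_caches):
            grad = grad + u.k_backward(grad, kc)
        grad = u.input_backward(grad, in_cache)
    return feats, scores, loss


class UnfoldedNet:
    """Explicit feedforward network with ``n`` tied residual blocks per unit.

    An independent evaluator (no shared recurrence loop): every block holds
    its own copies of the weights, so the forward pass is that of a plain
    deep ResNet whose depth grows linearly with ``n`` while the folded
    parameter count stays constant.
    """

    def __init__(self, net: FoldedNet, n: int):
        self.blocks = []
        for u in net.units:
            conv_in = _copy_conv(u.conv_in)
            norm_in = _copy_norm(u.norm_in)
            res = [( _copy_conv(u.conv_res), _copy_norm(u.norm_res))
                   for _ in range(n)]
            self.blocks.append((conv_in, norm_in, res))
        self.head = Linear(net.head.params["W"].shape[0],
                           net.head.params["W"].shape[1])
        self.head.params["W"] = net.head.params["W"].copy()
        self.head.params["b"] = net.head.params["b"].copy()
        self.depth = sum(1 + len(r) for _, _, r in self.blocks)

    def forward(self, images: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        x = np.asarray(images, dtype=float)
        if x.ndim == 3:
            x = x[:, None]
        h = x
        for conv_in, norm_in, res in self.blocks:
            h, _ = conv_in.forward(h)
            h, _ = norm_in.forward(h)
            h, _ = relu(h)
            for conv_r, norm_r in res:
                z, _ = conv_r.forward(h)
                z, _ = norm_r.forward(z)
                z, _ = relu(z)
                h = h + z
        feats, _ = global_avg_pool(h)
        scores, _ = self.head.forward(feats)
        return feats, scores


def _copy_conv(conv: Conv2d) -> Conv2d:
    new = Conv2d(conv.in_ch, conv.out_ch, conv.k, conv.stride)
    new.params["W"] = conv.params["W"].copy()
    new.params["b"] = conv.params["b"].copy()
    return new


def _copy_norm(norm: ChannelNorm) -> ChannelNorm:
    new = ChannelNorm(norm.params["gamma"].size, eps=norm.eps)
    new.params["gamma"] = norm.params["gamma"].copy()
    new.params["beta"] = norm.params["beta"].copy()
    return new


def unfold(net: FoldedNet, n: int) -> UnfoldedNet:
    """Materialize the equivalent explicit deep network with ``n`` tied
    residual blocks per unit; its forward pass matches ``forward(net, x, n)``."""
    if n < 0:
        raise ConfigurationError("unfold depth must be non-negative")
    return UnfoldedNet(net, n)
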