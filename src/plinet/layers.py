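"""Minimal NumPy neural-network layers with hand-coded backward passes.

Only what the architecture needs: 1-D convolution along the sequence axis
(vocabulary rows act as input channels), max pooling, dense layers, ReLU,
channel-concatenating inception blocks and the multi-dropout unit.  All
layers are pure functions of ``(input, params)``; parameters live in a flat
``dict[str, np.ndarray]`` keyed by ``"<layer name>/W"`` etc., and gradients
are accumulated into a dict of the same shape.  Dropout randomness comes
from an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv1D",
    "MaxPool1D",
    "ReLU",
    "Flatten",
    "Dense",
    "MultiDropout",
    "Inception1D",
    "Sequential",
]


class Layer:
    """Base class: subclasses implement forward/backward and declare params.

    ``param_specs`` maps a parameter name to ``(shape, fan_in, fan_out)``;
    fans of ``(0, 0)`` mark bias vectors (initialized to zero).
    """

    name: str

    def param_specs(self) -> dict[str, tuple[tuple[int, ...], int, int]]:
        return {}

    def forward(self, x, params, training=False, rng=None):
        raise NotImplementedError

    def backward(self, gy, cache, params, grads):
        raise NotImplementedError


class Conv1D(Layer):
    """Same-padded 1-D convolution: input ``(B, C_in, L)`` -> ``(B, C_out, L)``."""

    def __init__(self, name: str, c_in: int, c_out: int, kernel: int):
        self.name = name
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.pad_l = (kernel - 1) // 2
        self.pad_r = kernel - 1 - self.pad_l

    def param_specs(self):
        k = self.kernel
        return {
            f"{self.name}/W": ((self.c_out, self.c_in * k), self.c_in * k, self.c_out * k),
            f"{self.name}/b": ((self.c_out,), 0, 0),
        }

    def forward(self, x, params, training=False, rng=None):
        B, C, L = x.shape
        if C != self.c_in:
            raise ValueError(f"{self.name}: expected {self.c_in} input channels, got {C}")
        W = params[f"{self.name}/W"]
        b = params[f"{self.name}/b"]
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad_l, self.pad_r)))
        # (B, C, L, k) -> (B*L, C*k)
        cols = sliding_window_view(xp, self.kernel, axis=2)
        cols2 = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(B * L, C * self.kernel)
        y = cols2 @ W.T + b
        y = y.reshape(B, L, self.c_out).transpose(0, 2, 1)
        return y, (cols2, (B, C, L))

    def backward(self, gy, cache, params, grads):
        cols2, (B, C, L) = cache
        k = self.kernel
        W = params[f"{self.name}/W"]
        g2 = np.ascontiguousarray(gy.transpose(0, 2, 1)).reshape(B * L, self.c_out)
        grads[f"{self.name}/W"] = grads.get(f"{self.name}/W", 0) + g2.T @ cols2
        grads[f"{self.name}/b"] = grads.get(f"{self.name}/b", 0) + g2.sum(axis=0)
        gcols = (g2 @ W).reshape(B, L, C, k)
        gxp = np.zeros((B, C, L + k - 1))
        for t in range(k):
            gxp[:, :, t : t + L] += gcols[:, :, :, t].transpose(0, 2, 1)
        return gxp[:, :, self.pad_l : self.pad_l + L]


class MaxPool1D(Layer):
    """Max pooling along the sequence axis; ``same=True`` keeps the length."""

    def __init__(self, name: str, width: int, stride: int, same: bool = False):
        self.name = name
        self.width, self.stride, self.same = width, stride, same
        if same and stride != 1:
            raise ValueError("same-length pooling requires stride 1")
        self.pad_l = (width - 1) // 2 if same else 0
        self.pad_r = width - 1 - self.pad_l if same else 0

    def out_length(self, L: int) -> int:
        if self.same:
            return L
        return (L - self.width) // self.stride + 1

    def forward(self, x, params, training=False, rng=None):
        B, C, L = x.shape
        if self.same:
            xp = np.pad(x, ((0, 0), (0, 0), (self.pad_l, self.pad_r)), constant_values=-np.inf)
        else:
            xp = x
        v = sliding_window_view(xp, self.width, axis=2)[:, :, :: self.stride]
        idx = v.argmax(axis=3)
        y = np.take_along_axis(v, idx[..., None], axis=3)[..., 0]
        return y, (idx, (B, C, L), xp.shape[2])

    def backward(self, gy, cache, params, grads):
        idx, (B, C, L), Lp = cache
        Lo = gy.shape[2]
        pos = idx + self.stride * np.arange(Lo)[None, None, :]
        gxp = np.zeros((B, C, Lp))
        bi, ci, _ = np.indices(idx.shape)
        np.add.at(gxp, (bi, ci, pos), gy)
        return gxp[:, :, self.pad_l : self.pad_l + L]


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        self.name = name

    def forward(self, x, params, training=False, rng=None):
        mask = x > 0
        return x * mask, mask

    def backward(self, gy, cache, params, grads):
        return gy * cache


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        self.name = name

    def forward(self, x, params, training=False, rng=None):
        return x.reshape(x.shape[0], -1), x.shape

    def backward(self, gy, cache, params, grads):
        return gy.reshape(cache)


class Dense(Layer):
    """Affine layer: ``(B, n_in) -> (B, n_out)`` with ``y = x W^T + b``."""

    def __init__(self, name: str, n_in: int, n_out: int):
        self.name = name
        self.n_in, self.n_out = n_in, n_out

    def param_specs(self):
        return {
            f"{self.name}/W": ((self.n_out, self.n_in), self.n_in, self.n_out),
            f"{self.name}/b": ((self.n_out,), 0, 0),
        }

    def forward(self, x, params, training=False, rng=None):
        y = x @ params[f"{self.name}/W"].T + params[f"{self.name}/b"]
        return y, x

    def backward(self, gy, cache, params, grads):
        x = cache
        grads[f"{self.name}/W"] = grads.get(f"{self.name}/W", 0) + gy.T @ x
        grads[f"{self.name}/b"] = grads.get(f"{self.name}/b", 0) + gy.sum(axis=0)
        return gy @ params[f"{self.name}/W"]


class MultiDropout(Layer):
    """Several dropout units applied in parallel, combined by weighted mean.

    Each unit ``u`` applies an independent inverted-scaling dropout mask at
    its own rate; the layer output is the weighted mean of the unit outputs,
    which collapses to an elementwise multiplier ``M = sum_u w_u m_u/(1-r_u)``.
    In inference mode the layer is the identity.
    """

    def __init__(self, name: str, rates: Sequence[float], weights: Sequence[float]):
        self.name = name
        rates = tuple(float(r) for r in rates)
        weights = tuple(float(w) for w in weights)
        if len(rates) != len(weights):
            raise ValueError("multi-dropout needs one weight per unit rate")
        if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("multi-dropout weights must be nonnegative and sum to 1")
        if any(not (0 <= r < 1) for r in rates):
            raise ValueError("dropout rates must lie in [0, 1)")
        self.rates, self.weights = rates, weights

    def forward(self, x, params, training=False, rng=None):
        if not training:
            return x, None
        if rng is None:
            raise ValueError("multi-dropout in training mode needs an rng")
        M = np.zeros_like(x)
        for r, w in zip(self.rates, self.weights):
            if r == 0.0:
                M += w
            else:
                mask = rng.random(x.shape) >= r
                M += (w / (1.0 - r)) * mask
        return x * M, M

    def backward(self, gy, cache, params, grads):
        if cache is None:
            return gy
        return gy * cache


class Inception1D(Layer):
    """Parallel 1-, 3- and 5-wide convolutions plus a 3-wide max-pool branch.

    Each conv branch is followed by ReLU; the pool branch passes its input
    channels through unchanged.  Branch outputs are concatenated along the
    channel axis, so ``out_channels = 3 * branch_channels + c_in``.
    """

    def __init__(self, name: str, c_in: int, branch_channels: int):
        self.name = name
        self.c_in = c_in
        self.branch_channels = branch_channels
        self.convs = [Conv1D(f"{name}/conv{k}", c_in, branch_channels, k) for k in (1, 3, 5)]
        self.relus = [ReLU(f"{name}/relu{k}") for k in (1, 3, 5)]
        self.pool = MaxPool1D(f"{name}/pool", width=3, stride=1, same=True)
        self.out_channels = 3 * branch_channels + c_in

    def param_specs(self):
        specs = {}
        for conv in self.convs:
            specs.update(conv.param_specs())
        return specs

    def forward(self, x, params, training=False, rng=None):
        outs, caches = [], []
        for conv, relu in zip(self.convs, self.relus):
            y, c1 = conv.forward(x, params, training, rng)
            y, c2 = relu.forward(y, params, training, rng)
            outs.append(y)
            caches.append((c1, c2))
        yp, cp = self.pool.forward(x, params, training, rng)
        outs.append(yp)
        return np.concatenate(outs, axis=1), (caches, cp)

    def backward(self, gy, cache, params, grads):
        caches, cp = cache
        b = self.branch_channels
        gx = self.pool.backward(gy[:, 3 * b :, :], cp, params, grads)
        for i, (conv, relu) in enumerate(zip(self.convs, self.relus)):
            g = gy[:, i * b : (i + 1) * b, :]
            c1, c2 = caches[i]
            g = relu.backward(g, c2, params, grads)
            gx = gx + conv.backward(g, c1, params, grads)
        return gx


class Sequential(Layer):
    def __init__(self, name: str, layers: Sequence[Layer]):
        self.name = name
        self.layers = list(layers)

    def param_specs(self):
        specs = {}
        for layer in self.layers:
            specs.update(layer.param_specs())
        return specs

    def forward(self, x, params, training=False, rng=None):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x, params, training, rng)
            caches.append(c)
        return x, caches

    def backward(self, gy, cache, params, grads):
        for layer, c in zip(reversed(self.layers), reversed(cache)):
            gy = layer.backward(gy, c, params, grads)
        return gy
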