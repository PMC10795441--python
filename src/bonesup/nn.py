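"""Minimal CPU neural-network layers with manual backprop.

Purpose-built for the translation networks in this package: 2-D convolution
(im2col), instance normalization, nearest-neighbor upsampling, ReLU /
LeakyReLU / Tanh, residual blocks, and Adam. Forward passes are functional —
``forward`` returns ``(output, tape)`` and ``backward`` consumes the tape —
so the same network can appear several times in one computation graph (as
the cycle-consistency objective requires). All math is float32, NCHW layout,
single-threaded numpy; runs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "InstanceNorm2d",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "UpsampleNearest2x",
    "Sequential",
    "ResBlock",
    "Adam",
]

F32 = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray):  # -> (y, ctx)
        raise NotImplementedError

    def backward(self, dy: np.ndarray, ctx, accumulate: bool = True) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """Zero-padded 2-D convolution via im2col; backward uses k^2 shifted adds."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1, pad: int = 0,
                 rng: np.random.Generator | None = None, w_sd: float = 0.02):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(rng.normal(0.0, w_sd, size=(c_out, c_in, k, k)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def _cols(self, x: np.ndarray):
        k, s, p = self.k, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, ho, wo = win.shape[:4]
        # (n, ho, wo, c, k, k) -> rows of length c*k*k
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * ho * wo, -1)
        return cols, (n, ho, wo, x.shape)

    def forward(self, x: np.ndarray):
        cols, (n, ho, wo, padded_shape) = self._cols(x)
        wf = self.W.value.reshape(self.c_out, -1)
        y = cols @ wf.T + self.b.value
        y = y.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)
        return np.ascontiguousarray(y), (cols, padded_shape, x.shape)

    def backward(self, dy, ctx, accumulate=True):
        cols, padded_shape, x_shape = ctx
        n, _, ho, wo = dy.shape
        dflat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        if accumulate:
            self.W.grad += (dflat.T @ cols).reshape(self.W.value.shape)
            self.b.grad += dflat.sum(axis=0)
        dcols = dflat @ self.W.value.reshape(self.c_out, -1)
        dcols = dcols.reshape(n, ho, wo, self.c_in, self.k, self.k)
        k, s, p = self.k, self.stride, self.pad
        dxp = np.zeros(padded_shape, dtype=F32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return np.ascontiguousarray(dxp.reshape(x_shape))


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalization over H, W with affine parameters."""

    def __init__(self, c: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + F32(self.eps))
        xhat = (x - mu) * inv
        y = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        return y.astype(F32), (xhat.astype(F32), inv.astype(F32))

    def backward(self, dy, ctx, accumulate=True):
        xhat, inv = ctx
        if accumulate:
            self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
            self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        m1 = dy.mean(axis=(2, 3), keepdims=True)
        m2 = (dy * xhat).mean(axis=(2, 3), keepdims=True)
        return (g * inv * (dy - m1 - xhat * m2)).astype(F32)


class ReLU(Layer):
    def forward(self, x):
        mask = x > 0
        return x * mask, mask

    def backward(self, dy, ctx, accumulate=True):
        return dy * ctx


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = F32(slope)

    def forward(self, x):
        mask = x > 0
        return np.where(mask, x, self.slope * x), mask

    def backward(self, dy, ctx, accumulate=True):
        return np.where(ctx, dy, self.slope * dy)


class Tanh(Layer):
    def forward(self, x):
        y = np.tanh(x)
        return y, y

    def backward(self, dy, ctx, accumulate=True):
        return dy * (1.0 - ctx * ctx)


class UpsampleNearest2x(Layer):
    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3), x.shape

    def backward(self, dy, ctx, accumulate=True):
        n, c, h2, w2 = dy.shape
        return dy.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)).astype(F32)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        ctxs = []
        for l in self.layers:
            x, c = l.forward(x)
            ctxs.append(c)
        return x, ctxs

    def backward(self, dy, ctx, accumulate=True):
        for l, c in zip(reversed(self.layers), reversed(ctx)):
            dy = l.backward(dy, c, accumulate)
        return dy


class ResBlock(Layer):
    """conv-IN-ReLU-conv-IN with an identity skip connection."""

    def __init__(self, c: int, rng: np.random.Generator):
        self.body = Sequential(
            Conv2d(c, c, 3, pad=1, rng=rng),
            InstanceNorm2d(c),
            ReLU(),
            Conv2d(c, c, 3, pad=1, rng=rng),
            InstanceNorm2d(c),
        )

    def params(self):
        return self.body.params()

    def forward(self, x):
        y, ctx = self.body.forward(x)
        return x + y, ctx

    def backward(self, dy, ctx, accumulate=True):
        return dy + self.body.backward(dy, ctx, accumulate)


class Adam:
    """Adam with the bias-corrected update; one instance per parameter group."""

    def __init__(self, params: list[Param], lr: float = 2e-4, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad * p.grad
            p.value -= (self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(F32)

    def state_dict(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v}
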