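"""Minimal NumPy neural-network layers with explicit backprop.

Conventions
-----------
* Image tensors are NCHW float32/float64 batches inside the network;
  the public pipeline API converts from single-image HWC at the edges.
* Every layer caches what its backward pass needs during ``forward``;
  ``backward(dy)`` consumes the cache and accumulates parameter
  gradients into ``Param.grad``.
* ``train=True`` switches batch-norm to batch statistics and enables
  dropout; evaluation mode is deterministic.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = [
    "Param",
    "Layer",
    "Sequential",
    "Residual",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "GELU",
    "Sigmoid",
    "Dense",
    "Dropout",
    "MaxPool2d",
    "GlobalAvgPool2d",
    "Flatten",
    "LayerNorm",
    "softmax",
    "softmax_cross_entropy",
]


class Param:
    """A trainable tensor together with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class: a differentiable module with parameters."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class Residual(Layer):
    """y = x + f(x), optionally with a projection on the skip path."""

    def __init__(self, body: Layer, skip: Layer | None = None):
        self.body = body
        self.skip = skip

    def params(self):
        ps = self.body.params()
        if self.skip is not None:
            ps = ps + self.skip.params()
        return ps

    def forward(self, x, train=False):
        y = self.body.forward(x, train=train)
        s = x if self.skip is None else self.skip.forward(x, train=train)
        return y + s

    def backward(self, dy):
        dx = self.body.backward(dy)
        ds = dy if self.skip is None else self.skip.backward(dy)
        return dx + ds


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * math.sqrt(2.0 / max(fan_in, 1))


class Conv2d(Layer):
    """2-D convolution (cross-correlation) via im2col + GEMM."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out = c_in, c_out
        self.k, self.stride = kernel, stride
        self.pad = (kernel - 1) // 2 if pad is None else pad
        fan_in = c_in * kernel * kernel
        self.W = Param(_he_init(rng, (fan_in, c_out), fan_in), "conv.W")
        self.b = Param(np.zeros(c_out), "conv.b") if bias else None
        self._cache = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        hp, wp = x.shape[2], x.shape[3]
        oh = (hp - k) // s + 1
        ow = (wp - k) // s + 1
        # (n, c, oh, ow, k, k)
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
        return np.ascontiguousarray(cols), (n, c, hp, wp, oh, ow)

    def forward(self, x, train=False):
        cols, meta = self._im2col(x)
        n, c, hp, wp, oh, ow = meta
        y = cols @ self.W.value
        if self.b is not None:
            y += self.b.value
        self._cache = (cols, meta)
        return y.reshape(n, oh, ow, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy):
        cols, (n, c, hp, wp, oh, ow) = self._cache
        k, s, p = self.k, self.stride, self.pad
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.c_out)
        self.W.grad += cols.T @ dyf
        if self.b is not None:
            self.b.grad += dyf.sum(axis=0)
        dcols = (dyf @ self.W.value.T).reshape(n, oh, ow, c, k, k)
        dxp = np.zeros((n, c, hp, wp))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if p:
            dxp = dxp[:, :, p:hp - p, p:wp - p]
        return dxp


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c), "bn.gamma")
        self.beta = Param(np.zeros(c), "bn.beta")
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy):
        xhat, inv, train, shape = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not train:
            return dy * g * inv[None, :, None, None]
        n = shape[0] * shape[2] * shape[3]
        dxhat = dy * g
        t1 = dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
        t2 = xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return inv[None, :, None, None] * (t1 - t2)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class GELU(Layer):
    """Exact (erf) form."""

    def forward(self, x, train=False):
        self._x = x
        return 0.5 * x * (1.0 + erf(x / math.sqrt(2.0)))

    def backward(self, dy):
        x = self._x
        cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
        return dy * (cdf + x * pdf)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dense(Layer):
    """Affine map on the last axis."""

    def __init__(self, d_in: int, d_out: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(_he_init(rng, (d_in, d_out), d_in), "dense.W")
        self.b = Param(np.zeros(d_out), "dense.b") if bias else None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=False):
        self._x = x
        y = x @ self.W.value
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, dy):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.W.grad += x2.T @ dy2
        if self.b is not None:
            self.b.grad += dy2.sum(axis=0)
        return (dy2 @ self.W.value.T).reshape(self._x.shape)


class Dropout(Layer):
    """Inverted dropout; identity in eval mode. ``rng`` is injected by the trainer."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        assert 0.0 <= p < 1.0
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class MaxPool2d(Layer):
    def __init__(self, kernel: int, stride: int, pad: int = 0):
        self.k, self.stride, self.pad = kernel, stride, pad

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        hp, wp = x.shape[2], x.shape[3]
        oh = (hp - k) // s + 1
        ow = (wp - k) // s + 1
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        flat = win.reshape(n, c, oh, ow, k * k)
        self._arg = flat.argmax(axis=-1)
        self._meta = (n, c, hp, wp, oh, ow)
        return flat.max(axis=-1)

    def backward(self, dy):
        n, c, hp, wp, oh, ow = self._meta
        k, s, p = self.k, self.stride, self.pad
        dxp = np.zeros((n, c, hp, wp))
        ii, jj = np.divmod(self._arg, k)
        gn, gc, gh, gw = np.meshgrid(np.arange(n), np.arange(c), np.arange(oh),
                                     np.arange(ow), indexing="ij")
        np.add.at(dxp, (gn, gc, gh * s + ii, gw * s + jj), dy)
        if p:
            dxp = dxp[:, :, p:hp - p, p:wp - p]
        return dxp


class GlobalAvgPool2d(Layer):
    """(N, C, H, W) -> (N, C), the arithmetic mean over spatial positions."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class LayerNorm(Layer):
    """Normalization over the last axis."""

    def __init__(self, d: int, eps: float = 1e-6):
        self.gamma = Param(np.ones(d), "ln.gamma")
        self.beta = Param(np.zeros(d), "ln.beta")
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * inv
        self._inv = inv
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dy):
        xhat, inv = self._xhat, self._inv
        red = tuple(range(dy.ndim - 1))
        self.gamma.grad += (dy * xhat).sum(axis=red)
        self.beta.grad += dy.sum(axis=red)
        dxhat = dy * self.gamma.value
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits, axis=-1)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n
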