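"""Feed-forward layers: dense, 1-D convolution, normalization, activations."""

from __future__ import annotations

import numpy as np

from . import core
from .core import Module, Parameter, glorot


class Dense(Module):
    """Affine map over the last axis: ``y = x @ W + b``."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.W = Parameter(glorot(rng, (d_in, d_out), d_in, d_out), "W")
        self.b = Parameter(np.zeros(d_out, dtype=core.DTYPE), "b") if bias else None

    def forward(self, x, train: bool = False):
        self._x = x
        y = x @ self.W.data
        if self.b is not None:
            y = y + self.b.data
        return y

    def backward(self, grad):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = grad.reshape(-1, grad.shape[-1])
        self.W.grad += x2.T @ g2
        if self.b is not None:
            self.b.grad += g2.sum(axis=0)
        return grad @ self.W.data.T


class Conv1d(Module):
    """1-D convolution on (N, C_in, L) with zero padding."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int | None = None,
    ):
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = c_in * kernel
        self.W = Parameter(glorot(rng, (c_out, c_in, kernel), fan_in, c_out), "W")
        self.b = Parameter(np.zeros(c_out, dtype=core.DTYPE), "b")

    def out_len(self, l_in: int) -> int:
        return (l_in + 2 * self.padding - self.kernel) // self.stride + 1

    def forward(self, x, train: bool = False):
        n, c, l_in = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        l_out = self.out_len(l_in)
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        # gather columns: (N, L_out, C_in * K)
        cols = np.empty((n, l_out, self.c_in, self.kernel), dtype=x.dtype)
        for k in range(self.kernel):
            cols[:, :, :, k] = xp[:, :, k: k + self.stride * l_out: self.stride].transpose(0, 2, 1)
        cols2 = cols.reshape(n * l_out, self.c_in * self.kernel)
        w2 = self.W.data.reshape(self.c_out, -1)
        y = (cols2 @ w2.T).reshape(n, l_out, self.c_out) + self.b.data
        self._cols2, self._xshape, self._lp = cols2, x.shape, xp.shape[-1]
        return y.transpose(0, 2, 1)

    def backward(self, grad):
        n, _, l_out = grad.shape
        g2 = grad.transpose(0, 2, 1).reshape(n * l_out, self.c_out)
        self.W.grad += (g2.T @ self._cols2).reshape(self.W.data.shape)
        self.b.grad += g2.sum(axis=0)
        gcols = (g2 @ self.W.data.reshape(self.c_out, -1)).reshape(
            n, l_out, self.c_in, self.kernel
        )
        gxp = np.zeros((n, self.c_in, self._lp), dtype=grad.dtype)
        for k in range(self.kernel):
            gxp[:, :, k: k + self.stride * l_out: self.stride] += gcols[:, :, :, k].transpose(0, 2, 1)
        p = self.padding
        return gxp[:, :, p: self._lp - p] if p else gxp


class ReLU(Module):
    def forward(self, x, train: bool = False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Mask RNG is per-instance."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x, train: bool = False):
        if not train or self.p <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class LayerNorm(Module):
    """Normalization over the last axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim, dtype=core.DTYPE), "gamma")
        self.beta = Parameter(np.zeros(dim, dtype=core.DTYPE), "beta")
        self.eps = eps

    def forward(self, x, train: bool = False):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.gamma.data * self._xhat + self.beta.data

    def backward(self, grad):
        xhat, inv = self._xhat, self._inv
        axes = tuple(range(grad.ndim - 1))
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        gh = grad * self.gamma.data
        d = xhat.shape[-1]
        return (
            gh - gh.mean(axis=-1, keepdims=True)
            - xhat * (gh * xhat).mean(axis=-1, keepdims=True)
        ) * inv


class BatchNorm1d(Module):
    """Per-channel batch normalization for (N, C, L) inputs."""

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels, dtype=core.DTYPE), "gamma")
        self.beta = Parameter(np.zeros(channels, dtype=core.DTYPE), "beta")
        self.running_mean = np.zeros(channels, dtype=core.DTYPE)
        self.running_var = np.ones(channels, dtype=core.DTYPE)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train: bool = False):
        if train:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            ).astype(core.DTYPE)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(core.DTYPE)
            self._m = x.shape[0] * x.shape[2]
        else:
            mu, var = self.running_mean, self.running_var
            self._m = None
        inv = 1.0 / np.sqrt(var + self.eps)
        self._inv = inv
        self._xhat = (x - mu[:, None]) * inv[:, None]
        return self.gamma.data[:, None] * self._xhat + self.beta.data[:, None]

    def backward(self, grad):
        xhat = self._xhat
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        gh = grad * self.gamma.data[:, None]
        if self._m is None:  # eval mode: running stats are constants
            return gh * self._inv[:, None]
        m = self._m
        return (
            gh
            - gh.sum(axis=(0, 2), keepdims=True) / m
            - xhat * (gh * xhat).sum(axis=(0, 2), keepdims=True) / m
        ) * self._inv[:, None]


class GlobalAvgPool(Module):
    """(N, C, L) -> (N, C) mean over the temporal axis."""

    def forward(self, x, train: bool = False):
        self._l = x.shape[-1]
        return x.mean(axis=-1)

    def backward(self, grad):
        return np.repeat(grad[:, :, None], self._l, axis=2) / self._l


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x, train: bool = False):
        for m in self.mods:
            x = m(x, train=train)
        return x

    def backward(self, grad):
        for m in reversed(self.mods):
            grad = m.backward(grad)
        return grad
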