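"""LSTM / bidirectional LSTM with full backpropagation through time."""

from __future__ import annotations

import numpy as np

from . import core
from .core import Module, Parameter, glorot, orthogonal


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTM(Module):
    """Single-layer unidirectional LSTM over (N, L, D) -> (N, L, H).

    Gate order in the fused weight matrices is (input, forget, cell, output).
    Forget-gate bias starts at 1 (standard trick for gradient flow).
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.d_in, self.hidden = d_in, hidden
        self.Wx = Parameter(glorot(rng, (d_in, 4 * hidden), d_in, 4 * hidden), "Wx")
        wh = np.concatenate([orthogonal(rng, (hidden, hidden)) for _ in range(4)], axis=1)
        self.Wh = Parameter(wh, "Wh")
        b = np.zeros(4 * hidden, dtype=core.DTYPE)
        b[hidden: 2 * hidden] = 1.0
        self.b = Parameter(b, "b")

    def forward(self, x, train: bool = False):
        n, L, _ = x.shape
        H = self.hidden
        h = np.zeros((n, H), dtype=x.dtype)
        c = np.zeros((n, H), dtype=x.dtype)
        self._x = x
        self._cache = []
        out = np.empty((n, L, H), dtype=x.dtype)
        xg = x @ self.Wx.data + self.b.data  # precompute input contribution
        for t in range(L):
            gates = xg[:, t] + h @ self.Wh.data
            i = _sigmoid(gates[:, :H])
            f = _sigmoid(gates[:, H: 2 * H])
            g = np.tanh(gates[:, 2 * H: 3 * H])
            o = _sigmoid(gates[:, 3 * H:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            out[:, t] = h
            self._cache.append((i, f, g, o, c_prev, tc, h_prev))
        return out

    def backward(self, grad):
        x = self._x
        n, L, _ = x.shape
        H = self.hidden
        dx = np.zeros_like(x)
        dh_next = np.zeros((n, H), dtype=x.dtype)
        dc_next = np.zeros((n, H), dtype=x.dtype)
        dWx = np.zeros_like(self.Wx.data)
        dWh = np.zeros_like(self.Wh.data)
        db = np.zeros_like(self.b.data)
        for t in reversed(range(L)):
            i, f, g, o, c_prev, tc, h_prev = self._cache[t]
            dh = grad[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dgates = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            dWx += x[:, t].T @ dgates
            dWh += h_prev.T @ dgates
            db += dgates.sum(axis=0)
            dx[:, t] = dgates @ self.Wx.data.T
            dh_next = dgates @ self.Wh.data.T
        self.Wx.grad += dWx
        self.Wh.grad += dWh
        self.b.grad += db
        return dx


class _Reverse(Module):
    def forward(self, x, train: bool = False):
        return x[:, ::-1]

    def backward(self, grad):
        return grad[:, ::-1]


class BiLSTM(Module):
    """Bidirectional LSTM; outputs forward/backward states concatenated."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.fwd = LSTM(d_in, hidden, rng)
        self.bwd = LSTM(d_in, hidden, rng)
        self.hidden = hidden

    def forward(self, x, train: bool = False):
        yf = self.fwd(x, train=train)
        yb = self.bwd(x[:, ::-1], train=train)[:, ::-1]
        return np.concatenate([yf, yb], axis=-1)

    def backward(self, grad):
        H = self.hidden
        gf = self.fwd.backward(np.ascontiguousarray(grad[..., :H]))
        gb = self.bwd.backward(np.ascontiguousarray(grad[:, ::-1, H:]))[:, ::-1]
        return gf + gb
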