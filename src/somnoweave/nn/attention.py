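"""Multi-head self-attention and post-norm transformer encoder blocks."""

from __future__ import annotations

import numpy as np

from .core import Module
from .layers import Dense, Dropout, LayerNorm, ReLU


def _softmax(x, axis=-1):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over (N, L, d)."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError(f"d_model {d_model} not divisible by n_heads {n_heads}")
        self.d_model, self.n_heads = d_model, n_heads
        self.d_head = d_model // n_heads
        self.wq = Dense(d_model, d_model, rng)
        self.wk = Dense(d_model, d_model, rng)
        self.wv = Dense(d_model, d_model, rng)
        self.wo = Dense(d_model, d_model, rng)

    def _split(self, x):
        n, L, _ = x.shape
        return x.reshape(n, L, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def _merge(self, x):
        n, h, L, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(n, L, h * dh)

    def forward(self, x, train: bool = False):
        q = self._split(self.wq(x, train=train))
        k = self._split(self.wk(x, train=train))
        v = self._split(self.wv(x, train=train))
        scale = float(1.0 / np.sqrt(self.d_head))  # python float: keeps dtype
        scores = (q @ k.transpose(0, 1, 3, 2)) * scale
        attn = _softmax(scores, axis=-1)
        ctx = attn @ v
        self._q, self._k, self._v, self._attn, self._scale = q, k, v, attn, scale
        return self.wo(self._merge(ctx), train=train)

    def backward(self, grad):
        gctx = self._split(self.wo.backward(grad))
        attn, q, k, v = self._attn, self._q, self._k, self._v
        gattn = gctx @ v.transpose(0, 1, 3, 2)
        gv = attn.transpose(0, 1, 3, 2) @ gctx
        # softmax backward per row
        gscores = attn * (gattn - (gattn * attn).sum(axis=-1, keepdims=True))
        gscores *= self._scale
        gq = gscores @ k
        gk = gscores.transpose(0, 1, 3, 2) @ q
        gx = self.wq.backward(self._merge(gq))
        gx = gx + self.wk.backward(self._merge(gk))
        gx = gx + self.wv.backward(self._merge(gv))
        return gx


class TransformerBlock(Module):
    """Post-norm encoder block: MHSA + residual + LN, FFN + residual + LN."""

    def __init__(
        self,
        d_model: int,
        n_heads: int,
        d_ff: int,
        rng: np.random.Generator,
        dropout: float = 0.1,
    ):
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.ln1 = LayerNorm(d_model)
        self.ff1 = Dense(d_model, d_ff, rng)
        self.relu = ReLU()
        self.ff2 = Dense(d_ff, d_model, rng)
        self.ln2 = LayerNorm(d_model)
        self.drop1 = Dropout(dropout, np.random.default_rng(rng.integers(2**31)))
        self.drop2 = Dropout(dropout, np.random.default_rng(rng.integers(2**31)))

    def forward(self, x, train: bool = False):
        a = self.ln1(x + self.drop1(self.attn(x, train=train), train=train), train=train)
        f = self.ff2(self.relu(self.ff1(a, train=train), train=train), train=train)
        return self.ln2(a + self.drop2(f, train=train), train=train)

    def backward(self, grad):
        g = self.ln2.backward(grad)
        gf = self.ff1.backward(self.relu.backward(self.ff2.backward(self.drop2.backward(g))))
        ga = g + gf
        g1 = self.ln1.backward(ga)
        gx = self.attn.backward(self.drop1.backward(g1))
        return g1 + gx
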