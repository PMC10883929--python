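"""Multi-head self-attention and pre-norm transformer blocks (NumPy)."""

from __future__ import annotations

import math

import numpy as np

from .core import GELU, Dense, Dropout, Layer, LayerNorm, Sequential, softmax

__all__ = ["MultiHeadSelfAttention", "TransformerBlock"]


class MultiHeadSelfAttention(Layer):
    """Scaled dot-product self-attention over a (N, T, D) token batch."""

    def __init__(self, d: int, heads: int, rng: np.random.Generator | None = None):
        if d % heads:
            raise ValueError(f"embed dim {d} not divisible by {heads} heads")
        rng = rng or np.random.default_rng(0)
        self.d, self.h = d, heads
        self.dk = d // heads
        self.wq = Dense(d, d, rng=rng)
        self.wk = Dense(d, d, rng=rng)
        self.wv = Dense(d, d, rng=rng)
        self.wo = Dense(d, d, rng=rng)

    def params(self):
        return [p for l in (self.wq, self.wk, self.wv, self.wo) for p in l.params()]

    def _split(self, x):  # (N, T, D) -> (N, h, T, dk)
        n, t, _ = x.shape
        return x.reshape(n, t, self.h, self.dk).transpose(0, 2, 1, 3)

    def _merge(self, x):  # (N, h, T, dk) -> (N, T, D)
        n, h, t, dk = x.shape
        return x.transpose(0, 2, 1, 3).reshape(n, t, h * dk)

    def forward(self, x, train=False):
        q = self._split(self.wq.forward(x))
        k = self._split(self.wk.forward(x))
        v = self._split(self.wv.forward(x))
        scale = 1.0 / math.sqrt(self.dk)
        attn = softmax(np.einsum("nhtd,nhsd->nhts", q, k) * scale, axis=-1)
        ctx = np.einsum("nhts,nhsd->nhtd", attn, v)
        self._cache = (q, k, v, attn, scale)
        return self.wo.forward(self._merge(ctx))

    def backward(self, dy):
        q, k, v, attn, scale = self._cache
        dctx = self._split(self.wo.backward(dy))
        dattn = np.einsum("nhtd,nhsd->nhts", dctx, v)
        dv = np.einsum("nhts,nhtd->nhsd", attn, dctx)
        # softmax backward per row
        ds = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        ds *= scale
        dq = np.einsum("nhts,nhsd->nhtd", ds, k)
        dk = np.einsum("nhts,nhtd->nhsd", ds, q)
        dx = self.wq.backward(self._merge(dq))
        dx += self.wk.backward(self._merge(dk))
        dx += self.wv.backward(self._merge(dv))
        return dx

    def attention_rows(self, x: np.ndarray) -> np.ndarray:
        """Attention matrix for inspection/tests: rows sum to one."""
        self.forward(x)
        return self._cache[3]


class TransformerBlock(Layer):
    """Pre-norm encoder block: x + MHSA(LN(x)), then x + MLP(LN(x))."""

    def __init__(self, d: int, heads: int, mlp_ratio: float = 4.0,
                 dropout: float = 0.0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        hidden = int(round(d * mlp_ratio))
        self.ln1 = LayerNorm(d)
        self.attn = MultiHeadSelfAttention(d, heads, rng=rng)
        self.drop1 = Dropout(dropout, rng=rng)
        self.ln2 = LayerNorm(d)
        self.mlp = Sequential(Dense(d, hidden, rng=rng), GELU(),
                              Dense(hidden, d, rng=rng), Dropout(dropout, rng=rng))

    def params(self):
        return (self.ln1.params() + self.attn.params() + self.ln2.params()
                + self.mlp.params())

    def forward(self, x, train=False):
        x = x + self.drop1.forward(self.attn.forward(self.ln1.forward(x, train), train), train)
        x = x + self.mlp.forward(self.ln2.forward(x, train), train)
        return x

    def backward(self, dy):
        dx = dy + self.ln2.backward(self.mlp.backward(dy))
        dx = dx + self.ln1.backward(self.attn.backward(self.drop1.backward(dx)))
        return dx
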