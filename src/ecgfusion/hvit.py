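"""Reduced-depth transformer encoder over the slim-stem embedding.

The embedding map is flattened row-major into patch tokens, a learned
classification token is prepended and learned positional embeddings are
added. A pre-norm multi-head self-attention encoder follows, two layers
shallower than its reference configuration (ViT-Base: 12 layers, 12
heads, MLP ratio 4 -> depth 10 here). The feature vector is the flatten
of the last hidden states with the classification token removed, mapped
through one dense layer to the residual branch's feature dimension:

    F = W_f . Flatten(H) + b_f.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Dense, Layer, Param, TransformerBlock

__all__ = ["EncoderConfig", "HViTEncoder", "ViTFeatureHead",
           "tokenize", "encode", "vit_features", "build_hvit"]

REFERENCE_DEPTH = 12   # ViT-Base encoder depth


@dataclass
class EncoderConfig:
    reference_depth: int = REFERENCE_DEPTH
    embed_dim: int = 768
    heads: int = 12
    mlp_ratio: float = 4.0
    dropout: float = 0.0
    use_class_token: bool = True
    n_patches: int = 196               # 14 x 14

    def __post_init__(self):
        if self.embed_dim % self.heads:
            raise ValueError("embed_dim must be divisible by heads")
        if self.reference_depth < 2:
            raise ValueError("reference depth must be >= 2 so the "
                             "two-layer reduction is non-negative")
        side = int(round(self.n_patches ** 0.5))
        if side * side != self.n_patches:
            raise ValueError("n_patches must be a perfect square")

    @property
    def depth(self) -> int:
        """Encoder layers: two fewer than the reference configuration."""
        return self.reference_depth - 2

    @property
    def grid_side(self) -> int:
        return int(round(self.n_patches ** 0.5))


class HViTEncoder(Layer):
    """Tokenization + positional embedding + transformer encoder stack."""

    def __init__(self, cfg: EncoderConfig | None = None,
                 rng: np.random.Generator | None = None):
        self.cfg = cfg = cfg or EncoderConfig()
        rng = rng or np.random.default_rng(0)
        d = cfg.embed_dim
        self.cls_token = Param(rng.standard_normal((1, 1, d)) * 0.02, "cls")
        self.pos_embed = Param(rng.standard_normal((cfg.n_patches + 1, d)) * 0.02,
                               "pos")
        self.blocks = [TransformerBlock(d, cfg.heads, cfg.mlp_ratio,
                                        cfg.dropout, rng=rng)
                       for _ in range(cfg.depth)]

    @property
    def depth(self) -> int:
        return len(self.blocks)

    def params(self):
        ps = [self.cls_token, self.pos_embed]
        for b in self.blocks:
            ps += b.params()
        return ps

    # -- tokenization -------------------------------------------------------
    def tokenize(self, fmap: np.ndarray) -> np.ndarray:
        """(N, C, H, W) embedding map -> (N, n_patches + 1, D) tokens.

        The grid is flattened row-major (position (i, j) -> token i*W+j,
        offset by one for the class token); positional embeddings added.
        """
        n, c, h, w = fmap.shape
        cfg = self.cfg
        if h * w != cfg.n_patches or c != cfg.embed_dim:
            raise ValueError(f"feature map {h}x{w}x{c} does not match "
                             f"{cfg.grid_side}x{cfg.grid_side}x{cfg.embed_dim}")
        patches = fmap.transpose(0, 2, 3, 1).reshape(n, h * w, c)
        cls = np.broadcast_to(self.cls_token.value, (n, 1, c))
        tokens = np.concatenate([cls, patches], axis=1)
        return tokens + self.pos_embed.value

    def _detokenize_grad(self, dtokens: np.ndarray, shape) -> np.ndarray:
        n, c, h, w = shape
        self.pos_embed.grad += dtokens.sum(axis=0)
        self.cls_token.grad += dtokens[:, :1].sum(axis=0, keepdims=True)
        return dtokens[:, 1:].reshape(n, h, w, c).transpose(0, 3, 1, 2)

    # -- encoder ------------------------------------------------------------
    def encode(self, tokens: np.ndarray, train: bool = False) -> np.ndarray:
        """Run the block stack; return last hidden states without the
        class token: (N, n_patches, D)."""
        x = tokens
        for b in self.blocks:
            x = b.forward(x, train)
            if not np.all(np.isfinite(x)):
                raise FloatingPointError("non-finite activations in encoder")
        return x[:, 1:]

    def forward(self, fmap: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = fmap.shape
        return self.encode(self.tokenize(fmap), train)

    def backward(self, dh: np.ndarray) -> np.ndarray:
        n, p, d = dh.shape
        dx = np.zeros((n, p + 1, d))
        dx[:, 1:] = dh
        for b in reversed(self.blocks):
            dx = b.backward(dx)
        return self._detokenize_grad(dx, self._shape)


class ViTFeatureHead(Layer):
    """Dense reduction of the flattened hidden states to the fused width."""

    def __init__(self, n_patches: int, embed_dim: int, d_out: int,
                 rng: np.random.Generator | None = None):
        self.flatten_dim = n_patches * embed_dim
        self.d_out = d_out
        self.dense = Dense(self.flatten_dim, d_out, rng=rng or np.random.default_rng(0))

    def params(self):
        return self.dense.params()

    def forward(self, h: np.ndarray, train: bool = False) -> np.ndarray:
        n = h.shape[0]
        flat = h.reshape(n, -1)
        if flat.shape[1] != self.flatten_dim:
            raise ValueError(f"hidden states flatten to {flat.shape[1]}, "
                             f"head expects {self.flatten_dim}")
        self._hshape = h.shape
        return self.dense.forward(flat, train)

    def backward(self, dy):
        return self.dense.backward(dy).reshape(self._hshape)


def build_hvit(cfg: EncoderConfig | None = None, seed: int = 0) -> HViTEncoder:
    return HViTEncoder(cfg, rng=np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# single-sample functional wrappers

def tokenize(fmap_hwc: np.ndarray, model: HViTEncoder) -> np.ndarray:
    """(H, W, C) map -> (n_patches + 1, D) token matrix."""
    fmap = np.asarray(fmap_hwc, dtype=float).transpose(2, 0, 1)[None]
    return model.tokenize(fmap)[0]


def encode(tokens: np.ndarray, model: HViTEncoder) -> np.ndarray:
    """(T, D) tokens -> (n_patches, D) last hidden states."""
    return model.encode(np.asarray(tokens, dtype=float)[None])[0]


def vit_features(h: np.ndarray, head: ViTFeatureHead) -> np.ndarray:
    """F = W_f . Flatten(H) + b_f for a single hidden-state matrix."""
    return head.forward(np.asarray(h, dtype=float)[None])[0]
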