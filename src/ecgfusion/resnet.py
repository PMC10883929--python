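"""Residual-network feature extractor with the classifier head removed.

Residual blocks follow H_i = H_{i-1} + F(H_{i-1}); F is two 3x3
conv-BN pairs (basic block) or a 1x1/3x3/1x1 bottleneck, with a
projected skip when width or stride changes. The stem is a 3x3 stride-1
convolution into 64 filters followed by a 3x3 stride-2 max-pool
(batch-norm momentum 0.1, epsilon 1e-5). The extractor ends at the
global average pool: no dense classifier, so the feature vector length
equals the channel width entering the pool (512 for the 18-layer
configuration, 2048 for the 50-layer bottleneck one).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool2d,
    Layer,
    MaxPool2d,
    ReLU,
    Residual,
    Sequential,
)

__all__ = ["ResNetConfig", "ResidualBlock", "ResNetFeatureExtractor",
           "residual_block_forward", "resnet_features", "build_resnet"]


@dataclass
class ResNetConfig:
    initial_filters: int = 64
    blocks_per_stage: list[int] = field(default_factory=lambda: [2, 2, 2, 2])
    bottleneck: bool = False           # True -> 50-layer-style blocks
    input_size: int = 224
    in_channels: int = 3
    bn_momentum: float = 0.1
    bn_epsilon: float = 1e-5
    dropout: float = 0.35              # used only when a classifier head is attached
    weight_decay: float = 1e-4

    @classmethod
    def depth18(cls, **kw) -> "ResNetConfig":
        return cls(blocks_per_stage=[2, 2, 2, 2], bottleneck=False, **kw)

    @classmethod
    def depth50(cls, **kw) -> "ResNetConfig":
        return cls(blocks_per_stage=[3, 4, 6, 3], bottleneck=True, **kw)

    @property
    def feature_dim(self) -> int:
        """Channel width entering the global pool."""
        widest = self.initial_filters * 2 ** (len(self.blocks_per_stage) - 1)
        return widest * (4 if self.bottleneck else 1)


def _bn(c: int, cfg: ResNetConfig) -> BatchNorm2d:
    return BatchNorm2d(c, momentum=cfg.bn_momentum, eps=cfg.bn_epsilon)


class ResidualBlock(Residual):
    """Basic block: x + F(x), with projection when shape changes."""

    def __init__(self, c_in: int, c_out: int, stride: int, cfg: ResNetConfig,
                 rng: np.random.Generator):
        body = Sequential(
            Conv2d(c_in, c_out, 3, stride=stride, rng=rng), _bn(c_out, cfg),
            ReLU(),
            Conv2d(c_out, c_out, 3, stride=1, rng=rng), _bn(c_out, cfg),
        )
        skip = None
        if stride != 1 or c_in != c_out:
            skip = Sequential(Conv2d(c_in, c_out, 1, stride=stride, rng=rng),
                              _bn(c_out, cfg))
        super().__init__(body, skip)
        self.post = ReLU()

    def forward(self, x, train=False):
        return self.post.forward(super().forward(x, train), train)

    def backward(self, dy):
        return super().backward(self.post.backward(dy))


class BottleneckBlock(Residual):
    """1x1 reduce -> 3x3 -> 1x1 expand (x4), plus skip."""

    expansion = 4

    def __init__(self, c_in: int, width: int, stride: int, cfg: ResNetConfig,
                 rng: np.random.Generator):
        c_out = width * self.expansion
        body = Sequential(
            Conv2d(c_in, width, 1, rng=rng), _bn(width, cfg), ReLU(),
            Conv2d(width, width, 3, stride=stride, rng=rng), _bn(width, cfg), ReLU(),
            Conv2d(width, c_out, 1, rng=rng), _bn(c_out, cfg),
        )
        skip = None
        if stride != 1 or c_in != c_out:
            skip = Sequential(Conv2d(c_in, c_out, 1, stride=stride, rng=rng),
                              _bn(c_out, cfg))
        super().__init__(body, skip)
        self.post = ReLU()

    def forward(self, x, train=False):
        return self.post.forward(super().forward(x, train), train)

    def backward(self, dy):
        return super().backward(self.post.backward(dy))


class ResNetFeatureExtractor(Layer):
    """Stem -> residual stages -> global average pool -> feature vector."""

    def __init__(self, cfg: ResNetConfig | None = None,
                 rng: np.random.Generator | None = None):
        self.cfg = cfg = cfg or ResNetConfig()
        rng = rng or np.random.default_rng(0)
        f = cfg.initial_filters
        self.stem = Sequential(
            Conv2d(cfg.in_channels, f, 3, stride=1, rng=rng), _bn(f, cfg), ReLU(),
            MaxPool2d(3, stride=2, pad=1),
        )
        layers: list[Layer] = []
        c_in = f
        for i, n_blocks in enumerate(cfg.blocks_per_stage):
            width = f * (2 ** i)
            for b in range(n_blocks):
                stride = 2 if (b == 0 and i > 0) else 1
                if cfg.bottleneck:
                    blk = BottleneckBlock(c_in, width, stride, cfg, rng)
                    c_in = width * BottleneckBlock.expansion
                else:
                    blk = ResidualBlock(c_in, width, stride, cfg, rng)
                    c_in = width
                layers.append(blk)
        self.stages = Sequential(*layers)
        self.pool = GlobalAvgPool2d()
        self.feature_dim = c_in
        assert self.feature_dim == cfg.feature_dim

    def params(self):
        return self.stem.params() + self.stages.params()

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if h != self.cfg.input_size or w != self.cfg.input_size:
            raise ValueError(f"expected {self.cfg.input_size}-pixel input, "
                             f"got {h}x{w}")
        x = self.stem.forward(x, train)
        x = self.stages.forward(x, train)
        return self.pool.forward(x, train)

    def backward(self, dy):
        dy = self.pool.backward(dy)
        dy = self.stages.backward(dy)
        return self.stem.backward(dy)


def build_resnet(cfg: ResNetConfig | None = None, seed: int = 0) -> ResNetFeatureExtractor:
    return ResNetFeatureExtractor(cfg, rng=np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# single-sample functional wrappers

def residual_block_forward(x_hwc: np.ndarray, block: Residual) -> np.ndarray:
    """x + F(x) for a single (H, W, C) feature map."""
    x = np.asarray(x_hwc, dtype=float).transpose(2, 0, 1)[None]
    return block.forward(x)[0].transpose(1, 2, 0)


def resnet_features(image_hwc: np.ndarray, model: ResNetFeatureExtractor) -> np.ndarray:
    """Feature vector of a single (H, W, C) image; length = feature_dim."""
    x = np.asarray(image_hwc, dtype=float)
    if x.ndim == 2:
        x = x[..., None]
    return model.forward(x.transpose(2, 0, 1)[None])[0]
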