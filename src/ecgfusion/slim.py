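"""The "slim" multibranch convolutional patch-embedding stem.

Replaces the single 16x16 patch-embedding convolution of a standard
vision transformer with four downsampling stage modules followed by a
pointwise channel expansion. Each stage sums a 3x3 stride-2 backbone
branch with a 1x1 stride-2 shortcut branch,

    O(x) = F_s2(x) + L_s2(x),

then refines at constant resolution with two stride-1 branches plus the
identity, gated by squeeze-and-excitation channel attention:

    H(x) = SE[ F_s1(O) + L_s1(O) + O ].

Every convolution is followed by batch normalization and ReLU. At the
default configuration a 224x224 image maps through spatial sizes
224 -> 112 -> 56 -> 28 -> 14 with stage widths 48, 96, 192, 384, and the
final 1x1 convolution expands to 768 channels: a 14x14x768 embedding
map, token-compatible with a ViT-Base encoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    Dense,
    Layer,
    ReLU,
    Sequential,
    Sigmoid,
)

__all__ = ["SlimConfig", "SEBlock", "SlimStage", "SlimStem",
           "se_forward", "stage_forward", "slim_forward", "count_parameters",
           "build_slim_stem"]


@dataclass
class SlimConfig:
    stage_channels: list[int] = field(default_factory=lambda: [48, 96, 192, 384])
    final_channels: int = 768
    input_size: int = 224
    in_channels: int = 3
    se_reduction: int = 16

    def __post_init__(self):
        if len(self.stage_channels) != 4:
            raise ValueError("exactly four stage modules are required")
        if self.input_size % 16:
            raise ValueError("input size must be divisible by 2^4")
        if self.se_reduction < 1:
            raise ValueError("se_reduction must be >= 1")

    @property
    def output_size(self) -> int:
        return self.input_size // 16


class SEBlock(Layer):
    """Squeeze-and-excitation: global pool -> bottleneck FCs -> sigmoid gates."""

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        hidden = max(1, channels // reduction)
        self.channels = channels
        self.fc1 = Dense(channels, hidden, rng=rng)
        self.relu = ReLU()
        self.fc2 = Dense(hidden, channels, rng=rng)
        self.sigmoid = Sigmoid()

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def gates(self, x: np.ndarray) -> np.ndarray:
        z = x.mean(axis=(2, 3))                      # squeeze: (N, C)
        g = self.sigmoid.forward(self.fc2.forward(self.relu.forward(self.fc1.forward(z))))
        return g

    def forward(self, x, train=False):
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        g = self.gates(x)
        self._x, self._g = x, g
        return x * g[:, :, None, None]

    def backward(self, dy):
        x, g = self._x, self._g
        dx = dy * g[:, :, None, None]
        dg = (dy * x).sum(axis=(2, 3))               # (N, C)
        dz = self.fc1.backward(self.relu.backward(self.fc2.backward(self.sigmoid.backward(dg))))
        h, w = x.shape[2], x.shape[3]
        dx += dz[:, :, None, None] / (h * w)
        return dx


def _conv_bn_relu(c_in: int, c_out: int, kernel: int, stride: int,
                  rng: np.random.Generator) -> Sequential:
    return Sequential(Conv2d(c_in, c_out, kernel, stride=stride, rng=rng),
                      BatchNorm2d(c_out), ReLU())


class SlimStage(Layer):
    """One downsampling stage: two stride-2 branches, two stride-1 branches
    plus identity, SE gating."""

    def __init__(self, c_in: int, c_out: int, se_reduction: int = 16,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.f_s2 = _conv_bn_relu(c_in, c_out, 3, 2, rng)
        self.l_s2 = _conv_bn_relu(c_in, c_out, 1, 2, rng)
        self.f_s1 = _conv_bn_relu(c_out, c_out, 3, 1, rng)
        self.l_s1 = _conv_bn_relu(c_out, c_out, 1, 1, rng)
        self.se = SEBlock(c_out, se_reduction, rng=rng)

    def params(self):
        return [p for m in (self.f_s2, self.l_s2, self.f_s1, self.l_s1, self.se)
                for p in m.params()]

    def downsample(self, x, train=False):
        """O(x): the summed stride-2 branches (halves H and W)."""
        if x.shape[2] % 2 or x.shape[3] % 2:
            raise ValueError(f"stage input must have even spatial size, "
                             f"got {x.shape[2]}x{x.shape[3]}")
        return self.f_s2.forward(x, train) + self.l_s2.forward(x, train)

    def forward(self, x, train=False):
        o = self.downsample(x, train)
        s = self.f_s1.forward(o, train) + self.l_s1.forward(o, train) + o
        return self.se.forward(s, train)

    def backward(self, dy):
        ds = self.se.backward(dy)
        do = self.f_s1.backward(ds) + self.l_s1.backward(ds) + ds
        return self.f_s2.backward(do) + self.l_s2.backward(do)


class SlimStem(Layer):
    """Four stage modules then the 1x1 channel-expansion convolution."""

    def __init__(self, cfg: SlimConfig | None = None,
                 rng: np.random.Generator | None = None):
        self.cfg = cfg = cfg or SlimConfig()
        rng = rng or np.random.default_rng(0)
        chans = [cfg.in_channels] + list(cfg.stage_channels)
        self.stages = [SlimStage(chans[i], chans[i + 1], cfg.se_reduction, rng)
                       for i in range(4)]
        self.expand = _conv_bn_relu(cfg.stage_channels[-1], cfg.final_channels,
                                    1, 1, rng)

    def params(self):
        return [p for s in self.stages for p in s.params()] + self.expand.params()

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if h != w or h != self.cfg.input_size:
            raise ValueError(
                f"expected square {self.cfg.input_size}-pixel input, got {h}x{w}")
        for s in self.stages:
            x = s.forward(x, train)
        return self.expand.forward(x, train)

    def backward(self, dy):
        dy = self.expand.backward(dy)
        for s in reversed(self.stages):
            dy = s.backward(dy)
        return dy

    def intermediate_shapes(self) -> list[tuple[int, int]]:
        """(input spatial size, output channels) per stage, then the 1x1."""
        cfg = self.cfg
        out = []
        size = cfg.input_size
        for c in cfg.stage_channels:
            out.append((size, c))
            size //= 2
        out.append((size, cfg.final_channels))
        return out


def build_slim_stem(cfg: SlimConfig | None = None, seed: int = 0) -> SlimStem:
    return SlimStem(cfg, rng=np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# single-image HWC wrappers

def _to_nchw(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        x = x[..., None]
    return x.transpose(2, 0, 1)[None]


def _to_hwc(x: np.ndarray) -> np.ndarray:
    return x[0].transpose(1, 2, 0)


def se_forward(x_hwc: np.ndarray, se: SEBlock) -> np.ndarray:
    """SE gating of a single (H, W, C) feature map."""
    return _to_hwc(se.forward(_to_nchw(x_hwc)))


def stage_forward(x_hwc: np.ndarray, stage: SlimStage) -> np.ndarray:
    """One stage module applied to a single (H, W, C) feature map."""
    return _to_hwc(stage.forward(_to_nchw(x_hwc)))


def slim_forward(image_hwc: np.ndarray, stem: SlimStem) -> np.ndarray:
    """Full stem on a single (H, W, C) image -> (H/16, W/16, final) map."""
    return _to_hwc(stem.forward(_to_nchw(image_hwc)))


def count_parameters(cfg: SlimConfig | None = None) -> int:
    """Deterministic trainable-parameter count for a configuration."""
    return build_slim_stem(cfg).n_parameters()
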