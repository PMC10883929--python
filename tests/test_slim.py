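import numpy as np
import pytest

from conftest import naive_conv2d
from ecgfusion.slim import (
    SEBlock,
    SlimConfig,
    SlimStage,
    build_slim_stem,
    count_parameters,
    se_forward,
    slim_forward,
    stage_forward,
)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------------
# squeeze-and-excitation

def test_se_gate_saturation_limits(rng):
    se = SEBlock(8, reduction=2, rng=rng)
    x = rng.standard_normal((1, 8, 4, 4))
    se.fc2.b.value[:] = 50.0           # gates -> 1
    np.testing.assert_allclose(se.forward(x), x, atol=1e-12)
    se.fc2.b.value[:] = -50.0          # gates -> 0
    np.testing.assert_allclose(se.forward(x), 0.0, atol=1e-12)


def test_se_matches_hand_composition(rng):
    se = SEBlock(8, reduction=2, rng=rng)
    x = rng.standard_normal((1, 8, 4, 4))
    got = se.forward(x)
    # independent pool -> fc -> relu -> fc -> sigmoid -> scale
    z = x[0].mean(axis=(1, 2))
    h = np.maximum(z @ se.fc1.W.value + se.fc1.b.value, 0.0)
    g = _sigmoid(h @ se.fc2.W.value + se.fc2.b.value)
    np.testing.assert_allclose(got[0], x[0] * g[:, None, None], atol=1e-12)
    assert np.all((g > 0) & (g < 1))


def test_se_is_channelwise_contraction(rng):
    se = SEBlock(6, reduction=3, rng=rng)
    x = rng.standard_normal((2, 6, 5, 5))
    y = se.forward(x)
    assert np.all(np.abs(y) <= np.abs(x) + 1e-12)


def test_se_hwc_wrapper(rng):
    se = SEBlock(8, reduction=2, rng=rng)
    x = rng.standard_normal((4, 4, 8))
    y = se_forward(x, se)
    assert y.shape == (4, 4, 8)


def test_se_channel_mismatch_rejected(rng):
    se = SEBlock(8, rng=rng)
    with pytest.raises(ValueError):
        se.forward(rng.standard_normal((1, 4, 4, 4)))


# ---------------------------------------------------------------------------
# stage module

def _identity_se(stage):
    stage.se.fc1.W.value[:] = 0.0
    stage.se.fc2.W.value[:] = 0.0
    stage.se.fc2.b.value[:] = 50.0


def test_stage_identity_limit_reduces_to_downsample(rng):
    """Zeroed stride-1 branches and unit SE gates leave only O(x)."""
    stage = SlimStage(3, 8, se_reduction=2, rng=rng)
    for branch in (stage.f_s1, stage.l_s1):
        branch.layers[0].W.value[:] = 0.0
    _identity_se(stage)
    x = rng.standard_normal((1, 3, 8, 8))
    np.testing.assert_allclose(stage.forward(x), stage.downsample(x),
                               atol=1e-9)


def test_stage_one_halves_224_to_112x48(rng):
    stage = SlimStage(3, 48, rng=np.random.default_rng(0))
    out = stage_forward(rng.standard_normal((224, 224, 3)), stage)
    assert out.shape == (112, 112, 48)


def test_stage_matches_direct_convolution_oracle(rng):
    """Full stage on an 8x8 input reproduced by naive loops to 1e-5."""
    stage = SlimStage(2, 4, se_reduction=2, rng=rng)
    x = rng.standard_normal((1, 2, 8, 8))
    got = stage.forward(x)[0]

    def branch(seq, inp, stride, pad):
        conv, bn, _ = seq.layers
        y = naive_conv2d(inp, conv.W.value, stride=stride, pad=pad)
        y += conv.b.value[:, None, None]
        y = (y - bn.running_mean[:, None, None]) / \
            np.sqrt(bn.running_var[:, None, None] + bn.eps)
        y = bn.gamma.value[:, None, None] * y + bn.beta.value[:, None, None]
        return np.maximum(y, 0.0)

    o = branch(stage.f_s2, x[0], 2, 1) + branch(stage.l_s2, x[0], 2, 0)
    s = branch(stage.f_s1, o, 1, 1) + branch(stage.l_s1, o, 1, 0) + o
    z = s.mean(axis=(1, 2))
    h = np.maximum(z @ stage.se.fc1.W.value + stage.se.fc1.b.value, 0.0)
    g = _sigmoid(h @ stage.se.fc2.W.value + stage.se.fc2.b.value)
    np.testing.assert_allclose(got, s * g[:, None, None], atol=1e-5)


def test_stage_rejects_odd_spatial_size(rng):
    stage = SlimStage(2, 4, rng=rng)
    with pytest.raises(ValueError):
        stage.forward(rng.standard_normal((1, 2, 7, 7)))


# ---------------------------------------------------------------------------
# full stem

def test_default_stem_emits_14x14x768(rng):
    stem = build_slim_stem(seed=0)
    out = slim_forward(rng.standard_normal((224, 224, 3)), stem)
    assert out.shape == (14, 14, 768)


def test_stem_intermediate_contract():
    stem = build_slim_stem(seed=0)
    assert stem.intermediate_shapes() == [(224, 48), (112, 96), (56, 192),
                                          (28, 384), (14, 768)]
    # probing after stage 3 directly
    x = np.zeros((1, 3, 224, 224))
    for s in stem.stages[:3]:
        x = s.forward(x)
    assert x.shape[1:] == (192, 28, 28)


def test_zero_input_zero_biases_gives_zero_output():
    cfg = SlimConfig(stage_channels=[4, 8, 16, 32], final_channels=64,
                     input_size=32, in_channels=1, se_reduction=2)
    stem = build_slim_stem(cfg, seed=1)
    out = slim_forward(np.zeros((32, 32, 1)), stem)
    np.testing.assert_allclose(out, 0.0, atol=1e-12)


def test_stem_rejects_wrong_size(rng):
    stem = build_slim_stem(SlimConfig(stage_channels=[4, 8, 16, 32],
                                      final_channels=64, input_size=32,
                                      in_channels=1), seed=0)
    with pytest.raises(ValueError):
        stem.forward(rng.standard_normal((1, 1, 48, 48)))


def test_config_validation():
    with pytest.raises(ValueError):
        SlimConfig(stage_channels=[48, 96, 192])
    with pytest.raises(ValueError):
        SlimConfig(input_size=100)
    with pytest.raises(ValueError):
        SlimConfig(se_reduction=0)


# ---------------------------------------------------------------------------
# parameter counting

def _expected_count(cfg: SlimConfig) -> int:
    total = 0
    c_in = cfg.in_channels
    for c in cfg.stage_channels:
        for k, cin in ((3, c_in), (1, c_in), (3, c), (1, c)):
            total += cin * k * k * c + c     # conv W + b
            total += 2 * c                   # BN gamma + beta
        hid = max(1, c // cfg.se_reduction)
        total += c * hid + hid + hid * c + c
        c_in = c
    total += c_in * cfg.final_channels + cfg.final_channels
    total += 2 * cfg.final_channels
    return total


def test_count_parameters_arithmetic_oracle():
    cfg = SlimConfig(stage_channels=[1, 1, 1, 1], final_channels=1,
                     input_size=32, in_channels=1, se_reduction=1)
    assert count_parameters(cfg) == _expected_count(cfg)
    cfg2 = SlimConfig(stage_channels=[4, 8, 16, 32], final_channels=24,
                      input_size=32, in_channels=1, se_reduction=2)
    assert count_parameters(cfg2) == _expected_count(cfg2)


def test_doubling_reduction_halves_se_weights():
    a = SlimConfig(stage_channels=[8, 16, 32, 64], final_channels=32,
                   input_size=32, se_reduction=2)
    b = SlimConfig(stage_channels=[8, 16, 32, 64], final_channels=32,
                   input_size=32, se_reduction=4)
    def se_weights(cfg):
        return sum(2 * c * max(1, c // cfg.se_reduction)
                   for c in cfg.stage_channels)
    assert se_weights(a) == 2 * se_weights(b)
    assert count_parameters(a) > count_parameters(b)


def test_default_count_positive_and_stable():
    assert count_parameters() == count_parameters() > 0
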