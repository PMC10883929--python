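import numpy as np
import pytest

from ecgfusion.synthetic import generate_record, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def clean_record_100():
    """100 noiseless healthy beats with truth peaks."""
    return generate_record("Healthy Control", n_beats=100, fs=360,
                           noise_snr_db=None, seed=3)


@pytest.fixture(scope="session")
def dataset_48():
    """Balanced 12-class beat-image set, 20 per class, 48-px renders."""
    _manifest, ds = make_dataset(n_per_class=20, fs=360, noise_snr_db=20,
                                 seed=5, image_size=48)
    return ds


def naive_conv2d(x, w, stride=1, pad=0):
    """Direct-loop convolution oracle. x: (C,H,W); w: (C*k*k, C_out) in the
    same (c, ki, kj) unrolling as the GEMM path; returns (C_out, OH, OW)."""
    c, h, wd = x.shape
    k = int(round((w.shape[0] / c) ** 0.5))
    c_out = w.shape[1]
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    oh = (x.shape[1] - k) // stride + 1
    ow = (x.shape[2] - k) // stride + 1
    out = np.zeros((c_out, oh, ow))
    wk = w.reshape(c, k, k, c_out)
    for co in range(c_out):
        for i in range(oh):
            for j in range(ow):
                acc = 0.0
                for ci in range(c):
                    for ki in range(k):
                        for kj in range(k):
                            acc += x[ci, i * stride + ki, j * stride + kj] * wk[ci, ki, kj, co]
                out[co, i, j] = acc
    return out


def finite_diff_grad(f, x, eps=1e-5):
    """Central-difference gradient of scalar f at x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
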