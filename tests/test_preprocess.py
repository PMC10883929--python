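import numpy as np
import pytest

from ecgfusion.preprocess import (
    DenoiseConfig,
    PeakDetectorConfig,
    SegmentationConfig,
    WindowCost,
    detect_r_peaks,
    dwt_denoise,
    optimize_window,
    resample_record,
    segment_beats,
    window_from_constant,
)
from ecgfusion.synthetic import generate_record


# ---------------------------------------------------------------------------
# denoising

def test_denoise_zeros_stay_zero():
    out = dwt_denoise(np.zeros(1024))
    assert out.shape == (1024,)
    np.testing.assert_allclose(out, 0.0)


def test_denoise_identity_when_threshold_zero(rng):
    x = rng.standard_normal(1000)
    out = dwt_denoise(x, DenoiseConfig(threshold_scale=0.0))
    np.testing.assert_allclose(out, x, atol=1e-8)


def test_denoise_preserves_length_and_works_per_lead(rng):
    x = rng.standard_normal((777, 3))
    out = dwt_denoise(x)
    assert out.shape == x.shape
    # column independence: denoising a single column matches the matrix path
    np.testing.assert_allclose(out[:, 1], dwt_denoise(x[:, 1]))


def test_denoise_snr_gain_at_5db():
    sr = generate_record("Healthy Control", n_beats=30, fs=360,
                         noise_snr_db=5.0, seed=7)
    clean, noisy = sr.clean_reference, sr.record.signal

    def snr(x):
        return 10 * np.log10(np.sum(clean ** 2) / np.sum((x - clean) ** 2))

    gain = snr(dwt_denoise(noisy)) - snr(noisy)
    assert gain >= 3.0


def test_denoise_errors(rng):
    with pytest.raises(ValueError):
        dwt_denoise(rng.standard_normal(64), DenoiseConfig(level=9))
    with pytest.raises(Exception):
        dwt_denoise(rng.standard_normal(512), DenoiseConfig(wavelet="nosuch"))
    with pytest.raises(ValueError):
        dwt_denoise(np.array([1.0, np.nan, 2.0]))


# ---------------------------------------------------------------------------
# R-peak detection

def test_flat_signal_yields_no_peaks():
    assert detect_r_peaks(np.zeros(3600), 360).size == 0


def test_detection_on_100_clean_beats(clean_record_100):
    sr = clean_record_100
    det = detect_r_peaks(sr.record.lead("II"), 360)
    truth = sr.truth_r_peaks
    hits = sum(1 for t in truth if np.min(np.abs(det - t)) <= 10)
    assert hits >= 99
    assert len(det) <= len(truth) + 1


def test_single_beat_single_peak():
    sr = generate_record("Healthy Control", n_beats=1, fs=360,
                         noise_snr_db=None, seed=11)
    det = detect_r_peaks(sr.record.lead("II"), 360)
    assert len(det) == 1
    assert abs(det[0] - sr.truth_r_peaks[0]) <= 10


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_peaks_increasing_and_refractory_on_noise(seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(3000)
    cfg = PeakDetectorConfig()
    det = detect_r_peaks(x, 360, cfg)
    if det.size > 1:
        gaps = np.diff(det)
        assert (gaps > 0).all()
        assert (gaps >= int(cfg.refractory * 360)).all()


def test_detection_input_validation():
    with pytest.raises(ValueError):
        detect_r_peaks(np.zeros(5000), 50)          # fs too low
    with pytest.raises(ValueError):
        detect_r_peaks(np.zeros(100), 360)          # shorter than learning phase


# ---------------------------------------------------------------------------
# segmentation

def _record(n=3000, leads=2, fs=360.0):
    from ecgfusion.io import ECGRecord
    rng = np.random.default_rng(5)
    return ECGRecord(signal=rng.standard_normal((n, leads)), fs=fs,
                     lead_names=["I", "II"][:leads], record_id="t")


def test_segment_slices_match_expected_window():
    rec = _record()
    segs = segment_beats(rec, [1000, 2000])
    assert len(segs) == 2
    for seg, p in zip(segs, [1000, 2000]):
        assert seg.values.shape == (651, 2)
        assert seg.r_index_local == 250
        np.testing.assert_array_equal(seg.values, rec.signal[p - 250:p + 401])


def test_boundary_drop_and_pad():
    rec = _record()
    assert segment_beats(rec, [100]) == []
    segs = segment_beats(rec, [100],
                         SegmentationConfig(boundary_policy="pad-edge"))
    assert len(segs) == 1 and segs[0].segment_length == 651
    np.testing.assert_array_equal(segs[0].values[:150],
                                  np.tile(rec.signal[0], (150, 1)))


def test_segment_edge_cases():
    rec = _record()
    assert segment_beats(rec, []) == []
    with pytest.raises(ValueError):
        segment_beats(rec, [1000], SegmentationConfig(left=-1))
    with pytest.raises(ValueError):
        segment_beats(rec, [5000])


def test_segment_length_identity():
    cfg = SegmentationConfig(left=10, right=20)
    segs = segment_beats(_record(), [1000], cfg)
    assert segs[0].segment_length == cfg.left + cfg.right + 1 == 31


# ---------------------------------------------------------------------------
# window optimization

def test_single_candidate_is_returned():
    sr = generate_record("Healthy Control", n_beats=10, fs=360,
                         noise_snr_db=None, seed=0)
    wc = optimize_window([0.15], [sr])
    assert wc.W == 0.15
    assert wc.k == pytest.approx(54.0)


def test_window_closed_form():
    assert window_from_constant(54, 360) == pytest.approx(0.15)
    wc = WindowCost(W=window_from_constant(54, 360), fs=360)
    assert wc.k == pytest.approx(54.0)


def test_cost_identity():
    wc = WindowCost(W=0.1, miss_rate=0.1, false_rate=0.2, twave_overlap=0.3,
                    lam=2.0)
    assert wc.C == pytest.approx(0.1 + 0.2 + 2.0 * 0.3)


def test_grid_argmin_matches_brute_force():
    # noisy records make the candidates genuinely differ
    recs = [generate_record("Healthy Control", n_beats=12, fs=360,
                            noise_snr_db=0.0, seed=s) for s in (1, 2)]
    candidates = [0.05, 0.10, 0.15, 0.20]
    chosen = optimize_window(candidates, recs, lam=1.0)

    # independent brute force over the same grid
    def cost(W):
        tot = 0.0
        for r in recs:
            det = detect_r_peaks(r.record.lead("II"), 360,
                                 PeakDetectorConfig(mwi_window=W))
            truth = r.truth_r_peaks
            matched = np.zeros(len(truth), bool)
            false = overlap = 0
            for d in det:
                j = int(np.argmin(np.abs(truth - d)))
                if abs(truth[j] - d) <= 10 and not matched[j]:
                    matched[j] = True
                else:
                    false += 1
                if np.min(np.abs(r.t_apices - d)) < np.min(np.abs(truth - d)):
                    overlap += 1
            nd = max(len(det), 1)
            tot += (1 - matched.mean()) + false / nd + overlap / nd
        return tot / len(recs)

    costs = {W: cost(W) for W in candidates}
    best = min(sorted(candidates), key=lambda W: costs[W])
    assert chosen.W == best
    assert chosen.C == pytest.approx(costs[best])


def test_optimize_window_errors():
    with pytest.raises(ValueError):
        optimize_window([], [1])
    with pytest.raises(ValueError):
        optimize_window([0.1], [])


# ---------------------------------------------------------------------------
# resampling

def test_resample_preserves_duration():
    sr = generate_record("Healthy Control", n_beats=5, fs=250,
                         noise_snr_db=None, seed=1)
    out = resample_record(sr.record, 360.0)
    assert out.fs == 360.0
    assert out.n_samples == pytest.approx(sr.record.n_samples * 360 / 250, abs=2)
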