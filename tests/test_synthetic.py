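import numpy as np
import pytest

from ecgfusion.io import CLASS_NAMES, STANDARD_12_LEADS, BeatSegment
from ecgfusion.preprocess import SegmentationConfig, segment_beats
from ecgfusion.synthetic import (
    CLASS_SIGNATURES,
    BeatTemplate,
    generate_record,
    make_dataset,
    render_beat_image,
    st_window_means,
)


def test_signatures_cover_all_classes_and_are_distinct():
    assert set(CLASS_SIGNATURES) == set(CLASS_NAMES)
    hc = CLASS_SIGNATURES["Healthy Control"]
    assert not hc.st_offset and not hc.q_leads
    patterns = set()
    for name, sig in CLASS_SIGNATURES.items():
        if name != "Healthy Control":
            assert sig.st_offset or sig.q_leads or sig.t_invert
        patterns.add(tuple(sig.st_offset.get(l, 0.0) for l in STANDARD_12_LEADS))
    assert len(patterns) == len(CLASS_NAMES)  # separable from ST means alone


def test_template_invariants():
    with pytest.raises(ValueError):
        BeatTemplate(r=(0.05, 0.0, 0.012))      # R must dominate
    with pytest.raises(ValueError):
        BeatTemplate(p=(0.1, 0.5, 0.02))        # P after T


def test_healthy_st_near_baseline(clean_record_100):
    segs = segment_beats(clean_record_100.record,
                         clean_record_100.truth_r_peaks)
    m = st_window_means(segs[1], 360)
    assert np.all(np.abs(m) <= 0.02)


def test_inferior_signature_measured_on_leads():
    sr = generate_record("Inferior", n_beats=5, fs=360, noise_snr_db=None,
                         seed=1)
    segs = segment_beats(sr.record, sr.truth_r_peaks)
    base = st_window_means(
        segment_beats(generate_record("Healthy Control", n_beats=5, fs=360,
                                      noise_snr_db=None, seed=1).record,
                      sr.truth_r_peaks)[1], 360)
    m = st_window_means(segs[1], 360) - base
    idx = {l: i for i, l in enumerate(STANDARD_12_LEADS)}
    for lead in ("II", "III", "aVF"):
        assert m[idx[lead]] == pytest.approx(0.2, abs=0.05)
    for lead in ("I", "aVL", "V1", "V2", "V3"):
        assert m[idx[lead]] == pytest.approx(-0.2, abs=0.05)


def test_generation_deterministic():
    a = generate_record("Lateral", n_beats=4, fs=360, noise_snr_db=10, seed=9)
    b = generate_record("Lateral", n_beats=4, fs=360, noise_snr_db=10, seed=9)
    np.testing.assert_array_equal(a.record.signal, b.record.signal)
    np.testing.assert_array_equal(a.truth_r_peaks, b.truth_r_peaks)


def test_truth_peaks_match_clean_maxima(clean_record_100):
    sr = clean_record_100
    ii = STANDARD_12_LEADS.index("II")
    for p in sr.truth_r_peaks[:20]:
        lo, hi = p - 5, p + 6
        local = lo + np.argmax(sr.clean_reference[lo:hi, ii])
        assert abs(local - p) <= 2


def test_unknown_class_rejected():
    with pytest.raises(ValueError):
        generate_record("Septal-ish", n_beats=2)


# ---------------------------------------------------------------------------
# rendering

def _zero_beat(leads=12, length=651):
    return BeatSegment(values=np.zeros((length, leads)), r_index_local=250,
                       r_index_global=1000)


def test_zero_beat_renders_lane_center_lines():
    img = render_beat_image(_zero_beat(), size=48)[..., 0]
    lane = 48 // 12
    for j in range(12):
        band = img[j * lane:(j + 1) * lane]
        dark_rows = np.where((band < 0.99).any(axis=1))[0]
        # flat trace at the lane's vertical center
        assert dark_rows.size > 0
        assert set(dark_rows) <= {lane // 2 - 1, lane // 2}
        assert np.all(band[dark_rows] < 0.6)


def test_render_deterministic_and_bounded(clean_record_100):
    segs = segment_beats(clean_record_100.record,
                         clean_record_100.truth_r_peaks)
    a = render_beat_image(segs[0], size=64)
    b = render_beat_image(segs[0], size=64)
    np.testing.assert_array_equal(a, b)
    assert a.shape == (64, 64, 1)
    assert a.min() >= 0.0 and a.max() <= 1.0


def test_amplitude_change_is_lane_local():
    beat = _zero_beat()
    img0 = render_beat_image(beat, size=48)[..., 0]
    vals = beat.values.copy()
    vals[:, 3] = 0.8  # move lead aVR's trace
    img1 = render_beat_image(
        BeatSegment(values=vals, r_index_local=250, r_index_global=1000),
        size=48)[..., 0]
    lane = 48 // 12
    diff_rows = np.where((img0 != img1).any(axis=1))[0]
    assert diff_rows.size > 0
    assert diff_rows.min() >= 3 * lane and diff_rows.max() < 4 * lane


def test_grid_layout_shape():
    img = render_beat_image(_zero_beat(), size=48, layout="single-lead-grid")
    assert img.shape == (48, 48, 1)
    with pytest.raises(ValueError):
        render_beat_image(_zero_beat(), size=48, layout="circular")


# ---------------------------------------------------------------------------
# dataset assembly

def test_make_dataset_counts_and_balance(dataset_48):
    assert len(dataset_48) == 240
    assert dataset_48.images.shape == (240, 48, 48, 1)
    np.testing.assert_array_equal(np.bincount(dataset_48.labels),
                                  np.full(12, 20))


def test_make_dataset_seed_changes_content():
    _, a = make_dataset(2, classes=["Anterior"], seed=1, image_size=32)
    _, b = make_dataset(2, classes=["Anterior"], seed=2, image_size=32)
    assert a.images.shape == b.images.shape
    assert not np.array_equal(a.images, b.images)


def test_all_generated_beats_survive_segmentation():
    sr = generate_record("Posterior", n_beats=8, fs=360, noise_snr_db=None,
                         seed=4)
    segs = segment_beats(sr.record, sr.truth_r_peaks, SegmentationConfig())
    in_bounds = [p for p in sr.truth_r_peaks
                 if p - 250 >= 0 and p + 400 < sr.record.n_samples]
    assert len(segs) == len(in_bounds) == len(sr.truth_r_peaks)
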