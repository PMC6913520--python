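"""CSV dialect, filtering, R detection and median-beat construction."""

import numpy as np
import pytest

from hcmecg.ecg_io import (Ecg12Lead, EcgIoError, bandpass, detect_r_peaks,
                           median_beat, read_ecg, write_ecg)
from hcmecg.synthetic_data import make_archetype_library, synthesize_record

FS = 500.0


def make_record(samples, fs=FS, leads=("I", "II")):
    return Ecg12Lead("t", fs, leads, samples)


def test_read_csv_with_header_and_two_rows(tmp_path):
    p = tmp_path / "r.csv"
    p.write_text("# fs=500\ntime_s,I,II\n0.000,0.1,0.2\n0.002,0.3,0.4\n")
    rec = read_ecg(p)
    assert rec.n_samples == 2 and rec.fs == 500 and rec.lead_names == ("I", "II")


def test_fs_inferred_from_time_column(tmp_path):
    p = tmp_path / "r.csv"
    rows = "\n".join(f"{i/250:.4f},0.0" for i in range(5))
    p.write_text(f"time_s,V1\n{rows}\n")
    assert read_ecg(p).fs == pytest.approx(250.0)


def test_undeterminable_sampling_rate(tmp_path):
    p = tmp_path / "r.csv"
    p.write_text("I,II\n0.1,0.2\n")
    with pytest.raises(EcgIoError, match="sampling rate undeterminable"):
        read_ecg(p)


def test_duplicate_and_unknown_columns(tmp_path):
    p = tmp_path / "dup.csv"
    p.write_text("# fs=500\nI,I\n0.1,0.2\n")
    with pytest.raises(EcgIoError, match="duplicated"):
        read_ecg(p)
    q = tmp_path / "unk.csv"
    q.write_text("# fs=500\nI,XX\n0.1,0.2\n")
    with pytest.raises(EcgIoError, match="unknown lead"):
        read_ecg(q)


def test_non_numeric_cell(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("# fs=500\nI\nabc\n")
    with pytest.raises(EcgIoError, match="non-numeric"):
        read_ecg(p)


def test_write_read_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    rec = make_record(rng.standard_normal((100, 2)))
    write_ecg(rec, tmp_path / "w.csv")
    back = read_ecg(tmp_path / "w.csv")
    np.testing.assert_array_equal(back.samples, rec.samples)
    assert back.fs == rec.fs


def test_bandpass_removes_dc():
    rec = make_record(np.full((2000, 2), 0.7))
    out = bandpass(rec, 0.5, 100.0)
    trim = out.samples[200:-200]
    assert np.max(np.abs(trim)) < 1e-6


def test_bandpass_preserves_in_band_sinusoid():
    """1 Hz sinusoid in a 0.5-100 Hz band: measured amplitude matches the
    analytic forward-backward response |H(f)|^2 and stays within 1% of 1."""
    from scipy import signal as sps
    t = np.arange(20 * int(FS)) / FS
    x = np.sin(2 * np.pi * 1.0 * t)
    out = bandpass(make_record(np.column_stack([x, x])), 0.5, 100.0)
    mid = out.samples[5 * int(FS):-5 * int(FS), 0]
    # amplitude via projection over an integer number of cycles
    tm = t[5 * int(FS):-5 * int(FS)]
    c = np.column_stack([np.sin(2 * np.pi * tm), np.cos(2 * np.pi * tm)])
    amp = np.hypot(*np.linalg.lstsq(c, mid, rcond=None)[0])
    sos = sps.butter(4, [0.5, 100.0], btype="band", fs=FS, output="sos")
    _, h = sps.sosfreqz(sos, worN=[1.0], fs=FS)
    expected = np.abs(h[0]) ** 2  # filtfilt applies the filter twice
    assert amp == pytest.approx(expected, rel=1e-3)
    assert amp == pytest.approx(1.0, rel=0.01)


def test_bandpass_linearity():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((3000, 1))
    a = bandpass(make_record(x, leads=("I",)), 0.5, 100.0).samples
    b = bandpass(make_record(3.5 * x, leads=("I",)), 0.5, 100.0).samples
    np.testing.assert_allclose(b, 3.5 * a, rtol=1e-9, atol=1e-12)


def test_invalid_band_rejected():
    rec = make_record(np.zeros((1000, 2)))
    with pytest.raises(EcgIoError):
        bandpass(rec, 100.0, 0.5)
    with pytest.raises(EcgIoError):
        bandpass(rec, 10.0, 400.0)  # above Nyquist


def test_r_detection_on_synthetic_train(archetypes):
    rec = synthesize_record(archetypes["1B"], fs=FS, seed=0, n_beats=10,
                            hr_bpm=60)
    peaks = detect_r_peaks(rec, "II")
    assert len(peaks) == 10
    # truth: beat b has its alignment point at b*rr + 200 ms
    rr = int(60 / 60 * FS)
    truth = np.array([b * rr + int(0.2 * FS) for b in range(10)])
    err_ms = np.abs(np.array(peaks) - truth) / FS * 1000.0
    assert np.max(err_ms) <= 10.0


def test_r_detection_rate_invariance(archetypes):
    for hr in (50, 90):
        rec = synthesize_record(archetypes["1B"], fs=FS, seed=0, n_beats=8,
                                hr_bpm=hr)
        peaks = detect_r_peaks(rec, "II")
        rr = int(60 / hr * FS)
        truth = np.array([b * rr + int(0.2 * FS) for b in range(8)])
        assert len(peaks) == 8
        assert np.max(np.abs(np.array(peaks) - truth)) / FS * 1000.0 <= 10.0


def test_flat_record_yields_no_peaks():
    rec = make_record(np.zeros((3000, 2)))
    assert detect_r_peaks(rec, "I") == []


def test_refractory_enforced(archetypes):
    rec = synthesize_record(archetypes["2"], fs=FS, seed=1, n_beats=10)
    peaks = detect_r_peaks(rec, "V4")
    assert all(b - a >= 0.2 * FS for a, b in zip(peaks, peaks[1:]))


def test_median_beat_identity_and_robustness():
    rng = np.random.default_rng(2)
    beat = rng.standard_normal(200)
    rr = 400
    x = np.zeros(10 * rr + 400)
    peaks = []
    for b in range(10):
        start = b * rr + 100
        x[start:start + 200] += beat
        peaks.append(start + 100)
    rec = make_record(np.column_stack([x, x]))
    mb = median_beat(rec, "I", peaks, window_ms=300)
    half = int(0.150 * FS)
    np.testing.assert_allclose(
        mb.samples, x[peaks[0] - half:peaks[0] + half], atol=1e-12)
    # one corrupted beat does not move the median
    x2 = x.copy()
    x2[peaks[3] - half:peaks[3] + half] += 5.0
    mb2 = median_beat(make_record(np.column_stack([x2, x2])), "I", peaks,
                      window_ms=300)
    np.testing.assert_allclose(mb2.samples, mb.samples, atol=1e-12)
    assert mb.n_beats_used == 10


def test_median_beat_counts_only_full_windows():
    x = np.zeros(1000)
    rec = make_record(np.column_stack([x, x]))
    mb = median_beat(rec, "I", [10, 500, 995], window_ms=200)
    assert mb.n_beats_used == 1  # only the middle window fits


def test_median_beat_no_usable_beats():
    rec = make_record(np.zeros((100, 2)))
    with pytest.raises(EcgIoError, match="no usable beats"):
        median_beat(rec, "I", [5], window_ms=600)
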