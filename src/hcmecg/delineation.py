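"""Fiducial-point delineation and standard wave biomarkers on a median beat.

Thresholds are relative to the beat's own peak amplitude, so marks are
invariant to a positive gain.  Waves whose amplitude stays below the
estimated noise floor are reported absent rather than fabricated.
Conventions (documented, since the field has no single standard):

* QRS on/offset: outermost samples where |v| stays above 2% of the QRS peak
  (sustained-run criterion, 16 ms);
* R/S durations: zero-crossing width of the positive lobe containing the R
  peak / the negative lobe containing the S trough, clipped to the QRS;
* T end: where |v| falls below 5% of the T peak after it;
* T polarity: the sign of the signed area from QRS offset to T end, +1 for
  an exactly zero area (biphasic T waves are judged by area, not peak sign).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ecg_io import MedianBeat

__all__ = ["DelineationMarks", "WaveBiomarkers", "delineate", "wave_biomarkers"]

QRS_EDGE_FRAC = 0.02     # of QRS peak, for on/offset
T_END_FRAC = 0.05        # of T peak, for T end
SUSTAIN_MS = 16.0        # run length required below threshold
QRS_MAX_HALFWIDTH_MS = 90.0   # physiological cap on peak-to-edge distance
T_SEARCH_START_MS = 40.0   # gap after QRS offset before the T search window
T_SEARCH_SPAN_MS = 450.0


@dataclass
class DelineationMarks:
    """Sample indices of the fiducial points; ``None`` = wave not detected."""

    qrs_onset: int | None = None
    r_peak: int | None = None
    s_trough: int | None = None
    qrs_offset: int | None = None
    t_peak: int | None = None
    t_end: int | None = None

    def __post_init__(self):
        order = [self.qrs_onset, self.r_peak, self.qrs_offset,
                 self.t_peak, self.t_end]
        present = [m for m in order if m is not None]
        if any(b < a for a, b in zip(present, present[1:])):
            raise ValueError(f"marks out of order: {self}")
        if self.s_trough is not None:
            if self.r_peak is not None and self.s_trough < self.r_peak:
                raise ValueError("s_trough before r_peak")
            if self.qrs_offset is not None and self.s_trough > self.qrs_offset:
                raise ValueError("s_trough after qrs_offset")


@dataclass
class WaveBiomarkers:
    """Amplitude/width biomarkers of the QRS and T waves of one lead."""

    qrs_duration_ms: float
    r_duration_ms: float
    r_amplitude_mv: float
    s_duration_ms: float
    s_amplitude_mv: float   # reported as positive depth
    t_polarity: int         # +1 / -1
    t_amplitude_mv: float

    def __post_init__(self):
        for name in ("qrs_duration_ms", "r_duration_ms", "r_amplitude_mv",
                     "s_duration_ms", "s_amplitude_mv", "t_amplitude_mv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.t_polarity not in (+1, -1):
            raise ValueError("t_polarity must be +1 or -1")


def _expand(x, start, thr, sustain, direction, limit=None):
    """Walk from ``start`` until |x| stays < thr for ``sustain`` samples.

    Returns the last index (walking in ``direction``) with |x| >= thr,
    never beyond ``limit`` when given.
    """
    last = start
    run = 0
    i = start
    lo = 0 if limit is None or direction > 0 else max(limit, 0)
    hi = x.size if limit is None or direction < 0 else min(limit + 1, x.size)
    while lo <= i < hi:
        if abs(x[i]) >= thr:
            last = i
            run = 0
        else:
            run += 1
            if run >= sustain:
                break
        i += direction
    return last


def delineate(beat: MedianBeat, noise_window_ms: float = 80.0) -> DelineationMarks:
    """Locate QRS on/offset, R peak, S trough, T peak and T end.

    The QRS is searched around the beat's alignment point; the T wave in a
    window starting 40 ms after the QRS offset.  A flat beat (peak below
    5x the noise floor estimated from the leading samples) yields all-absent
    marks.
    """
    fs = beat.fs
    n = beat.samples.size
    if n * 1000.0 / fs < 400.0:
        raise ValueError("beat must contain at least 400 ms of signal")
    x = beat.samples - np.median(beat.samples)
    nw = max(int(noise_window_ms * fs / 1000.0), 2)
    noise = float(np.std(x[:nw]))
    peak = float(np.max(np.abs(x)))
    if peak < max(5.0 * noise, 0.02):
        return DelineationMarks()

    # QRS peak: largest |v| within +-80 ms of the alignment point
    half = int(0.080 * fs)
    a = max(beat.r_index - half, 0)
    b = min(beat.r_index + half + 1, n)
    p0 = a + int(np.argmax(np.abs(x[a:b])))
    qrs_amp = abs(x[p0])
    thr = max(QRS_EDGE_FRAC * qrs_amp, 2.0 * noise)
    sustain = max(int(SUSTAIN_MS * fs / 1000.0), 1)
    max_half = int(QRS_MAX_HALFWIDTH_MS * fs / 1000.0)
    onset = _expand(x, p0, thr, sustain, -1, limit=p0 - max_half)
    offset = _expand(x, p0, thr, sustain, +1, limit=p0 + max_half)

    seg = x[onset:offset + 1]
    r_peak = onset + int(np.argmax(seg)) if seg.max() > thr else None
    s_from = (r_peak if r_peak is not None else onset)
    sseg = x[s_from:offset + 1]
    s_trough = None
    if sseg.size and sseg.min() < -thr:
        s_trough = s_from + int(np.argmin(sseg))

    # T wave
    t_peak = t_end = None
    t0 = offset + int(T_SEARCH_START_MS * fs / 1000.0)
    t1 = min(offset + int(T_SEARCH_SPAN_MS * fs / 1000.0), n)
    if t1 - t0 > 2:
        tw = x[t0:t1]
        tp = t0 + int(np.argmax(np.abs(tw)))
        t_amp = abs(x[tp])
        if t_amp >= max(3.0 * noise, 0.02):
            t_peak = tp
            t_thr = T_END_FRAC * t_amp
            t_end = _expand(x, t_peak, t_thr, sustain, +1)
    return DelineationMarks(qrs_onset=onset, r_peak=r_peak, s_trough=s_trough,
                            qrs_offset=offset, t_peak=t_peak, t_end=t_end)


def _lobe_width(x, idx, lo, hi, positive: bool):
    """Zero-crossing width (in samples) of the lobe containing ``idx``."""
    a = idx
    cond = (lambda v: v > 0) if positive else (lambda v: v < 0)
    while a - 1 >= lo and cond(x[a - 1]):
        a -= 1
    b = idx
    while b + 1 <= hi and cond(x[b + 1]):
        b += 1
    return b - a + 1


def wave_biomarkers(beat: MedianBeat, marks: DelineationMarks) -> WaveBiomarkers:
    """Compute amplitude/width biomarkers from a beat and its marks.

    Absent waves contribute zero amplitude and duration; an exactly
    zero-area T is assigned polarity +1 by convention.
    """
    x = beat.samples - np.median(beat.samples)
    fs = beat.fs
    for m in (marks.qrs_onset, marks.qrs_offset):
        if m is not None and not (0 <= m < x.size):
            raise ValueError("marks outside the beat")
    if marks.qrs_onset is None or marks.qrs_offset is None:
        return WaveBiomarkers(0.0, 0.0, 0.0, 0.0, 0.0, +1, 0.0)
    on, off = marks.qrs_onset, marks.qrs_offset
    qrs_dur = (off - on) * 1000.0 / fs

    r_dur = r_amp = 0.0
    if marks.r_peak is not None and x[marks.r_peak] > 0:
        r_amp = float(x[marks.r_peak])
        r_dur = _lobe_width(x, marks.r_peak, on, off, True) * 1000.0 / fs
    s_dur = s_amp = 0.0
    if marks.s_trough is not None and x[marks.s_trough] < 0:
        s_amp = float(-x[marks.s_trough])
        s_dur = _lobe_width(x, marks.s_trough, on, off, False) * 1000.0 / fs

    t_pol, t_amp = +1, 0.0
    if marks.t_peak is not None and marks.t_end is not None:
        t_amp = float(abs(x[marks.t_peak]))
        area = float(np.trapezoid(x[off:marks.t_end + 1]))
        t_pol = -1 if area < 0 else +1

    qrs_dur = max(qrs_dur, r_dur, s_dur)  # lobes are clipped to the QRS
    return WaveBiomarkers(qrs_dur, r_dur, r_amp, s_dur, s_amp, t_pol, t_amp)
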