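"""Reading, writing and preprocessing of 12-lead ECG records.

CSV dialect: an optional leading metadata comment line ``# fs=500``, one
header row naming the lead columns (optionally preceded by a ``time_s``
column from which the sampling rate is inferred), values in mV.  A
WFDB-style dialect is accepted when the ``wfdb`` package is importable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "STANDARD_LEADS",
    "Ecg12Lead",
    "MedianBeat",
    "EcgIoError",
    "read_ecg",
    "write_ecg",
    "bandpass",
    "detect_r_peaks",
    "median_beat",
]

#: Conventional ordering of the 12 standard leads.
STANDARD_LEADS = ("I", "II", "III", "aVR", "aVL", "aVF",
                  "V1", "V2", "V3", "V4", "V5", "V6")


class EcgIoError(ValueError):
    """Raised for malformed ECG files or invalid processing parameters."""


@dataclass
class Ecg12Lead:
    """Multichannel ECG waveform record (samples in mV)."""

    subject_id: str
    fs: float
    lead_names: tuple
    samples: np.ndarray  # [n_samples, n_leads]

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.lead_names = tuple(self.lead_names)
        if self.fs <= 0:
            raise EcgIoError("sampling rate must be positive")
        if self.samples.ndim != 2 or self.samples.shape[1] != len(self.lead_names):
            raise EcgIoError("samples must be [n_samples, n_leads]")
        if len(set(self.lead_names)) != len(self.lead_names):
            raise EcgIoError("duplicated lead names")
        if len(self.lead_names) > 12:
            raise EcgIoError("at most 12 leads supported")
        if not np.all(np.isfinite(self.samples)):
            raise EcgIoError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        if name not in self.lead_names:
            raise KeyError(
                f"unknown lead {name!r}; record has {list(self.lead_names)}"
            )
        return self.samples[:, self.lead_names.index(name)]


@dataclass
class MedianBeat:
    """Representative beat of one lead.

    ``r_index`` is the alignment point used to stack the beats (the window
    center), not necessarily the positive R maximum for deep-S morphologies.
    """

    lead: str
    fs: float
    samples: np.ndarray
    r_index: int
    n_beats_used: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not (0 <= self.r_index < self.samples.size):
            raise EcgIoError("r_index outside beat")
        if self.n_beats_used < 1:
            raise EcgIoError("n_beats_used must be >= 1")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_ecg(path, dialect: str = "csv", subject_id: str | None = None) -> Ecg12Lead:
    """Read an ECG record.

    csv dialect: header row of lead names; sampling rate from a ``# fs=``
    comment line or inferred from a ``time_s`` column.  wfdb dialect needs
    the optional ``wfdb`` package.
    """
    path = Path(path)
    if dialect == "wfdb":
        try:
            import wfdb  # noqa: F401 - optional dependency
        except ImportError as e:
            raise EcgIoError(
                "wfdb dialect requires the optional 'wfdb' package"
            ) from e
        rec = wfdb.rdrecord(str(path.with_suffix("")))
        return Ecg12Lead(subject_id or path.stem, float(rec.fs),
                         tuple(rec.sig_name), np.asarray(rec.p_signal))
    if dialect != "csv":
        raise EcgIoError(f"unknown dialect {dialect!r}; expected 'csv' or 'wfdb'")

    if not path.exists():
        raise EcgIoError(f"file not found: {path}")
    fs_meta = None
    with open(path) as fh:
        first = fh.readline()
        while first.startswith("#"):
            stripped = first[1:].strip()
            if stripped.startswith("fs="):
                fs_meta = float(stripped.split("=", 1)[1])
            first = fh.readline()
        header = [h.strip() for h in first.rstrip("\n").split(",")]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise EcgIoError(f"duplicated lead columns: {dupes}")

    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    lead_cols = [c for c in df.columns if c != "time_s"]
    unknown = [c for c in lead_cols if c not in STANDARD_LEADS]
    if unknown:
        raise EcgIoError(
            f"unknown lead columns {unknown}; valid leads are {list(STANDARD_LEADS)}"
        )
    if not lead_cols:
        raise EcgIoError("no lead columns found")
    for c in lead_cols:
        if not pd.api.types.is_numeric_dtype(df[c]):
            raise EcgIoError(f"non-numeric values in column {c!r}")

    if fs_meta is not None:
        fs = fs_meta
    elif "time_s" in df.columns and len(df) >= 2:
        dt = np.diff(df["time_s"].to_numpy())
        if dt.size == 0 or np.any(dt <= 0):
            raise EcgIoError("sampling rate undeterminable: bad time_s column")
        fs = 1.0 / float(np.median(dt))
    else:
        raise EcgIoError(
            "sampling rate undeterminable: no '# fs=' metadata and no time_s column"
        )
    return Ecg12Lead(subject_id or path.stem, fs, tuple(lead_cols),
                     df[lead_cols].to_numpy(dtype=float))


def write_ecg(record: Ecg12Lead, path, time_column: bool = False) -> None:
    """Write a record in the CSV dialect (metadata line + header + rows)."""
    path = Path(path)
    df = pd.DataFrame(record.samples, columns=list(record.lead_names))
    if time_column:
        df.insert(0, "time_s", np.arange(record.n_samples) / record.fs)
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs:g}\n")
        df.to_csv(fh, index=False)  # default repr round-trips float64


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def bandpass(record: Ecg12Lead, low: float, high: float, order: int = 4) -> Ecg12Lead:
    """Zero-phase Butterworth band-pass (low may be 0 for a pure low-pass).

    Forward-backward filtering removes group delay so fiducial points keep
    their sample positions.
    """
    nyq = record.fs / 2.0
    if not (0 <= low < high < nyq):
        raise EcgIoError(
            f"band ({low}, {high}) Hz invalid for fs={record.fs} Hz "
            f"(need 0 <= low < high < {nyq})"
        )
    if low == 0:
        sos = sps.butter(order, high, btype="low", fs=record.fs, output="sos")
    else:
        sos = sps.butter(order, [low, high], btype="band", fs=record.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, record.samples, axis=0)
    return Ecg12Lead(record.subject_id, record.fs, record.lead_names, filtered)


def detect_r_peaks(
    record: Ecg12Lead,
    lead: str,
    refractory_ms: float = 200.0,
    threshold_frac: float = 0.4,
) -> list[int]:
    """Detect QRS alignment points on one lead.

    Amplitude-normalized derivative-energy detector: the squared first
    difference is smoothed over a 120 ms window and peaks above
    ``threshold_frac`` of the 98th percentile are kept, subject to a
    refractory period.  Each detection is refined to the maximum of |signal|
    nearby, which gives a consistent alignment point even for deep-S
    morphologies.  A flat record yields an empty list.
    """
    if record.duration_s < 2.0:
        raise EcgIoError("record shorter than 2 s; cannot detect beats")
    x = record.lead(lead)
    rng_amp = float(np.max(x) - np.min(x))
    if rng_amp < 1e-9:
        return []
    d = np.diff(x, prepend=x[0]) * record.fs  # mV/s
    energy = d * d
    win = max(int(round(0.120 * record.fs)), 1)
    env = np.convolve(energy, np.ones(win) / win, mode="same")
    thr = threshold_frac * np.percentile(env, 98)
    if thr <= 0:
        return []
    dist = max(int(round(refractory_ms / 1000.0 * record.fs)), 1)
    locs, _ = sps.find_peaks(env, height=thr, distance=dist)
    half = max(int(round(0.06 * record.fs)), 1)
    peaks = []
    for loc in locs:
        a, b = max(loc - half, 0), min(loc + half + 1, x.size)
        peaks.append(a + int(np.argmax(np.abs(x[a:b]))))
    # refinement can collapse neighbours; deduplicate and re-enforce refractory
    out: list[int] = []
    for p in sorted(set(peaks)):
        if not out or p - out[-1] >= dist:
            out.append(p)
    return out


def median_beat(
    record: Ecg12Lead,
    lead: str,
    r_peaks,
    window_ms: float = 600.0,
) -> MedianBeat:
    """Sample-wise median of R-aligned windows (half-open, centered).

    Only windows fully inside the record are used; the median makes the
    result robust to an occasional outlier beat.
    """
    x = record.lead(lead)
    half = int(round(window_ms / 2000.0 * record.fs))
    n_win = 2 * half
    stacks = []
    for r in r_peaks:
        a, b = r - half, r + half
        if a >= 0 and b <= x.size:
            stacks.append(x[a:b])
    if not stacks:
        raise EcgIoError(
            f"no usable beats for lead {lead!r}: no window of {window_ms} ms "
            "fits inside the record"
        )
    med = np.median(np.vstack(stacks), axis=0)
    return MedianBeat(lead=lead, fs=record.fs, samples=med,
                      r_index=half, n_beats_used=len(stacks))
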