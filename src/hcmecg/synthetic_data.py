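"""Synthetic 12-lead median beats and cohorts with known ground truth.

The study populations this package targets (Holter recordings of
hypertrophic-cardiomyopathy patients and healthy volunteers) are not
publicly deposited, so this module generates surrogate cohorts whose QRS
complexes are exact linear combinations of Hermite basis functions and whose
T waves are asymmetric Gaussian bumps of controllable polarity.  Four
built-in archetypes encode the qualitative phenotype contrasts:

* ``1A`` — normal QRS everywhere, inverted T waves in V4-V6;
* ``1B`` — identical QRS to 1A, upright T waves everywhere (except the
  physiologically negative aVR/V1);
* ``2``  — shorter R and deeper S in V4 (and neighbouring V3), V6 unchanged;
* ``3``  — short, low R with long, deep S in II and V4-V6 (wider QRS).

Because the QRS is generated *in* the Hermite basis, a noiseless fit must
recover the generating coefficients exactly, which anchors the whole
morphology pipeline to a known truth.  Inter-subject variability is a
coefficient of variation applied log-normally to widths/amplitudes and
normally (multiplicatively) to Hermite coefficients.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ecg_io import STANDARD_LEADS, Ecg12Lead, MedianBeat

__all__ = [
    "SyntheticArchetype",
    "SyntheticCohort",
    "make_archetype_library",
    "synthesize_beat",
    "synthesize_record",
    "synthesize_cohort",
    "write_cohort",
]

#: default beat layout: 600 ms window, basis (QRS) center at 200 ms
BEAT_WINDOW_MS = 600.0
QRS_CENTER_MS = 200.0
#: asymmetric-Gaussian T template: slow upstroke, faster downstroke (ms);
#: with the 170 ms default T-peak latency the truncated support leaves a
#: clearly isoelectric ST segment between QRS offset and T onset
T_SIGMA_LEFT_MS = 45.0
T_SIGMA_RIGHT_MS = 30.0
#: fraction of the peak used to define the truth on/offsets of each wave
QRS_SUPPORT_FRAC = 0.02
T_END_FRAC = 0.05


@dataclass
class SyntheticArchetype:
    """Parametric description of one phenotype's median beat, per lead."""

    name: str
    per_lead_qrs_coeffs: dict  # lead -> array of N Hermite coeffs (mV*ms^0.5)
    qrs_sigma_ms: dict         # lead -> width sigma (ms)
    t_polarity: dict           # lead -> +1 / -1
    t_amplitude_mv: dict       # lead -> positive amplitude (mV)
    t_peak_offset_ms: float = 170.0   # T peak latency after QRS offset
    variability: float = 0.05         # CV applied to continuous parameters
    noise_sd_mv: float = 0.0          # additive white noise SD

    def __post_init__(self):
        for lead, pol in self.t_polarity.items():
            if pol not in (+1, -1):
                raise ValueError(f"t_polarity[{lead}] must be +1 or -1, got {pol}")
        for lead, s in self.qrs_sigma_ms.items():
            if s <= 0:
                raise ValueError(f"qrs_sigma_ms[{lead}] must be positive")
        if self.noise_sd_mv < 0:
            raise ValueError("noise_sd_mv must be >= 0")
        if self.variability < 0:
            raise ValueError("variability must be >= 0")


@dataclass
class SyntheticCohort:
    """A generated cohort with its ground truth."""

    records: list            # list[Ecg12Lead]
    true_labels: list        # archetype name per subject
    true_params: list        # realized per-subject parameter dicts
    seed: int
    fs: float = 500.0

    def __post_init__(self):
        if len(self.records) != len(self.true_labels):
            raise ValueError("true_labels length must match records")

    @property
    def subject_ids(self) -> list:
        return [r.subject_id for r in self.records]


# ---------------------------------------------------------------------------
# archetype library
# ---------------------------------------------------------------------------

def _normal_qrs():
    """Normal-morphology QRS coefficients (c0..c3) and widths per lead.

    Values are package configuration chosen to give physiologically plausible
    amplitudes (dominant R ~1 mV precordially, rS in V1-V2) and the
    qualitative inter-archetype contrasts; they are not measured cohort
    statistics.
    """
    coeffs = {
        "I":   [2.0, -0.4, 0.15, 0.0],
        "II":  [3.6, -0.7, 0.20, 0.0],
        "III": [1.6, -0.3, 0.10, 0.0],
        "aVR": [-2.8, 0.5, -0.15, 0.0],
        "aVL": [1.2, -0.25, 0.10, 0.0],
        "aVF": [2.6, -0.5, 0.15, 0.0],
        "V1":  [-0.5, -2.5, 0.20, 0.0],
        "V2":  [0.5, -2.8, 0.30, 0.0],
        "V3":  [2.2, -1.8, 0.30, 0.0],
        "V4":  [5.0, -1.2, 0.30, 0.0],
        "V5":  [4.4, -1.0, 0.30, 0.0],
        "V6":  [3.8, -0.9, 0.25, 0.0],
    }
    sigma = {lead: 9.0 for lead in STANDARD_LEADS}
    return coeffs, sigma


def _t_defaults(inverted_lateral: bool):
    amp = {
        "I": 0.15, "II": 0.25, "III": 0.10, "aVR": 0.20, "aVL": 0.08,
        "aVF": 0.20, "V1": 0.10, "V2": 0.35, "V3": 0.40, "V4": 0.45,
        "V5": 0.35, "V6": 0.30,
    }
    pol = {lead: +1 for lead in STANDARD_LEADS}
    pol["aVR"] = -1   # physiologically discordant in every archetype
    pol["V1"] = -1
    if inverted_lateral:
        for lead in ("V4", "V5", "V6"):
            pol[lead] = -1
    return pol, amp


def make_archetype_library(variability: float = 0.05,
                           noise_sd_mv: float = 0.0) -> list[SyntheticArchetype]:
    """Return the four built-in phenotype archetypes (1A, 1B, 2, 3)."""
    coeffs_n, sigma_n = _normal_qrs()

    pol_1a, amp = _t_defaults(inverted_lateral=True)
    pol_up, _ = _t_defaults(inverted_lateral=False)

    a1a = SyntheticArchetype("1A", copy.deepcopy(coeffs_n), dict(sigma_n),
                             pol_1a, dict(amp),
                             variability=variability, noise_sd_mv=noise_sd_mv)
    a1b = SyntheticArchetype("1B", copy.deepcopy(coeffs_n), dict(sigma_n),
                             dict(pol_up), dict(amp),
                             variability=variability, noise_sd_mv=noise_sd_mv)

    # archetype 2: first Hermite bases altered in V4 and the neighbouring
    # precordials V3/V5: smaller c0 (lower/shorter R), strongly negative c1
    # (deep S), slightly narrower sigma; V6 and the limb leads untouched
    coeffs_2 = copy.deepcopy(coeffs_n)
    sigma_2 = dict(sigma_n)
    coeffs_2["V3"] = [0.90, -4.10, 0.95, 0.40]
    coeffs_2["V4"] = [1.10, -6.10, 1.50, 0.50]
    coeffs_2["V5"] = [1.80, -4.90, 1.20, 0.40]
    for lead in ("V3", "V4", "V5"):
        sigma_2[lead] = 8.0
    a2 = SyntheticArchetype("2", coeffs_2, sigma_2,
                            dict(pol_up), dict(amp),
                            variability=variability, noise_sd_mv=noise_sd_mv)

    # archetype 3: II and V4-V6 altered, wider QRS (longer S duration),
    # low/short R and deep/long S
    coeffs_3 = copy.deepcopy(coeffs_n)
    sigma_3 = dict(sigma_n)
    for lead, c in {
        "II": [1.4, -2.6, 0.50, 0.30],
        "V4": [1.6, -3.4, 0.70, 0.30],
        "V5": [1.5, -3.2, 0.70, 0.30],
        "V6": [1.4, -3.0, 0.60, 0.30],
    }.items():
        coeffs_3[lead] = c
        sigma_3[lead] = 13.0
    a3 = SyntheticArchetype("3", coeffs_3, sigma_3,
                            dict(pol_up), dict(amp),
                            variability=variability, noise_sd_mv=noise_sd_mv)
    return [a1a, a1b, a2, a3]


# ---------------------------------------------------------------------------
# beat synthesis
# ---------------------------------------------------------------------------

def _qrs_waveform(coeffs, sigma_ms, t_ms):
    from .hermite import hermite_basis
    out = np.zeros_like(t_ms)
    for n, c in enumerate(coeffs):
        if c != 0.0:
            out = out + c * hermite_basis(n, sigma_ms, t_ms)
    return out


#: the asymmetric-Gaussian T template is lifted and truncated at +-3 sigma so
#: it has compact support and leaves the ST segment and baseline exactly flat
T_TRUNC_SIGMAS = 3.0
_T_LIFT = float(np.exp(-0.5 * T_TRUNC_SIGMAS ** 2))
#: |v|/peak = 5% crossing of the lifted template, in sigma units
T_END_Z = float(np.sqrt(-2.0 * np.log(T_END_FRAC * (1.0 - _T_LIFT) + _T_LIFT)))


def _t_waveform(amp, polarity, t_peak_ms, t_ms):
    z = np.where(t_ms < t_peak_ms,
                 (t_ms - t_peak_ms) / T_SIGMA_LEFT_MS,
                 (t_ms - t_peak_ms) / T_SIGMA_RIGHT_MS)
    g = (np.exp(-0.5 * z * z) - _T_LIFT) / (1.0 - _T_LIFT)
    return polarity * amp * np.clip(g, 0.0, None)


def _support(x, frac):
    """First/last index where |x| reaches frac of its maximum."""
    a = np.abs(x)
    m = a.max()
    if m == 0:
        return None, None
    idx = np.nonzero(a >= frac * m)[0]
    return int(idx[0]), int(idx[-1])


def _beat_and_truth(coeffs, sigma_ms, t_pol, t_amp, t_peak_offset_ms, fs,
                    window_ms=BEAT_WINDOW_MS, center_ms=QRS_CENTER_MS):
    n = int(round(window_ms * fs / 1000.0))
    t_ms = np.arange(n) * 1000.0 / fs
    center_idx = int(round(center_ms * fs / 1000.0))
    qrs = _qrs_waveform(np.asarray(coeffs, float), sigma_ms, t_ms - center_ms)
    on, off = _support(qrs, QRS_SUPPORT_FRAC)
    if on is None:  # all-zero QRS
        on = off = center_idx
    t_peak_ms = t_ms[off] + t_peak_offset_ms
    if t_amp > 0:
        twave = _t_waveform(t_amp, t_pol, t_peak_ms, t_ms)
    else:
        twave = np.zeros_like(t_ms)
    clean = qrs + twave
    seg = qrs[on:off + 1]
    truth = {
        "center_index": center_idx,
        "qrs_onset": on,
        "qrs_offset": off,
        "r_peak": (on + int(np.argmax(seg))) if seg.size and seg.max() > 0 else None,
        "s_trough": (on + int(np.argmin(seg))) if seg.size and seg.min() < 0 else None,
        "t_peak": int(round(t_peak_ms * fs / 1000.0)) if t_amp > 0 else None,
        "t_end": int(round((t_peak_ms + T_SIGMA_RIGHT_MS * T_END_Z)
                           * fs / 1000.0)) if t_amp > 0 else None,
        "sigma_ms": sigma_ms,
        "coefficients": np.asarray(coeffs, float),
        "t_polarity": t_pol,
        "t_amplitude_mv": t_amp,
    }
    return clean, truth


def synthesize_beat(archetype: SyntheticArchetype, lead: str, fs: float = 500.0,
                    seed: int = 0, return_truth: bool = False):
    """Synthesize one median beat for ``lead`` (QRS in the Hermite basis).

    The beat spans 600 ms with the basis center (= ``MedianBeat.r_index``)
    at 200 ms; additive white noise of ``archetype.noise_sd_mv`` is applied.
    """
    if fs < 250:
        raise ValueError("fs must be >= 250 Hz")
    if lead not in archetype.per_lead_qrs_coeffs:
        raise KeyError(
            f"unknown lead {lead!r}; valid leads are "
            f"{sorted(archetype.per_lead_qrs_coeffs)}"
        )
    clean, truth = _beat_and_truth(
        archetype.per_lead_qrs_coeffs[lead],
        archetype.qrs_sigma_ms[lead],
        archetype.t_polarity[lead],
        archetype.t_amplitude_mv[lead],
        archetype.t_peak_offset_ms,
        fs,
    )
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, archetype.noise_sd_mv, clean.shape) \
        if archetype.noise_sd_mv > 0 else clean
    beat = MedianBeat(lead=lead, fs=fs, samples=noisy,
                      r_index=truth["center_index"], n_beats_used=1)
    return (beat, truth) if return_truth else beat


def _realize(archetype: SyntheticArchetype, rng) -> SyntheticArchetype:
    """Draw one subject's parameters around an archetype.

    Widths and amplitudes jitter log-normally (stays positive), Hermite
    coefficients jitter with a multiplicative normal factor of the stated CV.
    """
    cv = archetype.variability
    a = copy.deepcopy(archetype)
    if cv > 0:
        for lead in a.per_lead_qrs_coeffs:
            c = np.asarray(a.per_lead_qrs_coeffs[lead], float)
            a.per_lead_qrs_coeffs[lead] = c * (1.0 + cv * rng.standard_normal(c.shape))
            a.qrs_sigma_ms[lead] = float(a.qrs_sigma_ms[lead]
                                         * np.exp(cv * rng.standard_normal()))
            a.t_amplitude_mv[lead] = float(a.t_amplitude_mv[lead]
                                           * np.exp(cv * rng.standard_normal()))
        a.t_peak_offset_ms = float(a.t_peak_offset_ms
                                   * np.exp(cv * rng.standard_normal()))
    return a


def synthesize_record(archetype: SyntheticArchetype, subject_id: str = "s0",
                      fs: float = 500.0, seed: int = 0, n_beats: int = 8,
                      hr_bpm: float = 60.0) -> Ecg12Lead:
    """Tile beats of one (already realized) archetype into a 12-lead strip.

    Each beat gets fresh additive noise; the beat template itself is fixed,
    mimicking a steady rhythm.
    """
    rng = np.random.default_rng(seed)
    rr = int(round(60.0 / hr_bpm * fs))
    beat_len = int(round(BEAT_WINDOW_MS * fs / 1000.0))
    total = rr * n_beats + beat_len
    samples = np.zeros((total, len(STANDARD_LEADS)))
    for j, lead in enumerate(STANDARD_LEADS):
        clean, _ = _beat_and_truth(
            archetype.per_lead_qrs_coeffs[lead],
            archetype.qrs_sigma_ms[lead],
            archetype.t_polarity[lead],
            archetype.t_amplitude_mv[lead],
            archetype.t_peak_offset_ms,
            fs,
        )
        for b in range(n_beats):
            start = b * rr
            samples[start:start + beat_len, j] += clean
        if archetype.noise_sd_mv > 0:
            samples[:, j] += rng.normal(0.0, archetype.noise_sd_mv, total)
    return Ecg12Lead(subject_id, fs, STANDARD_LEADS, samples)


def synthesize_cohort(n_per_group: dict, variability: float = 0.05,
                      noise_sd: float = 0.02, fs: float = 500.0,
                      seed: int = 0, n_beats: int = 8) -> SyntheticCohort:
    """Generate a cohort of rhythm strips with recorded ground truth.

    ``n_per_group`` maps archetype names (subset of 1A/1B/2/3) to subject
    counts.  Each subject is an independent jitter of its archetype; the
    labels, realized parameters and the master seed are stored so cluster
    recovery can be scored against truth.
    """
    lib = {a.name: a for a in make_archetype_library(variability, noise_sd)}
    for name, cnt in n_per_group.items():
        if name not in lib:
            raise KeyError(f"unknown archetype {name!r}; valid: {sorted(lib)}")
        if cnt < 0:
            raise ValueError(f"negative subject count for group {name!r}")
    rng = np.random.default_rng(seed)
    records, labels, params = [], [], []
    i = 0
    for name in sorted(n_per_group):
        for _ in range(n_per_group[name]):
            realized = _realize(lib[name], rng)
            sid = f"s{i:04d}"
            rec_seed = int(rng.integers(0, 2**31 - 1))
            records.append(synthesize_record(realized, sid, fs, rec_seed,
                                             n_beats=n_beats))
            labels.append(name)
            params.append({
                "subject_id": sid,
                "archetype": name,
                "per_lead_qrs_coeffs": {k: np.asarray(v)
                                        for k, v in realized.per_lead_qrs_coeffs.items()},
                "qrs_sigma_ms": dict(realized.qrs_sigma_ms),
                "t_polarity": dict(realized.t_polarity),
                "t_amplitude_mv": dict(realized.t_amplitude_mv),
            })
            i += 1
    return SyntheticCohort(records, labels, params, seed=seed, fs=fs)


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write each record in the CSV dialect plus a labels CSV."""
    from .ecg_io import write_ecg
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in cohort.records:
        write_ecg(rec, out / f"{rec.subject_id}.csv")
    pd.DataFrame({
        "subject_id": cohort.subject_ids,
        "true_label": cohort.true_labels,
        "seed": cohort.seed,
    }).to_csv(out / "labels.csv", index=False)
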