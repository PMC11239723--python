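"""Fiducial measurements on ECG records, independent of any generator.

These estimators recover the class-defining quantities of the eight-class
vocabulary — PR interval (first-degree AV block), RR-interval variability
(atrial fibrillation), QRS duration and precordial amplitude pattern (bundle
branch blocks), prematurity (PAC/PVC) and ST-segment level (STD/STE) — from
the waveform alone.  They deliberately share no code or bookkeeping with the
synthetic generator so they can serve as its independent check, and they are
also usable as plain feature extractors for baseline probes.

All routines operate on the signal in millivolts and return seconds /
millivolts.  Detection runs on a lightly smoothed copy of a single
measurement lead (lead II by default, the customary rhythm lead).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .ecg_io import ECGRecord

__all__ = [
    "detect_r_peaks",
    "measure_rr_intervals",
    "rr_coefficient_of_variation",
    "measure_pr_interval",
    "measure_qrs_widths",
    "measure_st_level",
    "qrs_amplitude_ratio_v1_v6",
    "class_checks",
    "feature_vector",
    "FEATURE_NAMES",
]

_SMOOTH_S = 0.012  # smoothing window for detection, seconds


def _lead(record: ECGRecord, name: str = "II") -> np.ndarray:
    if name in record.lead_names:
        x = record.signal[record.lead_names.index(name)]
    else:  # single-lead or unnamed data: use the first channel
        x = record.signal[0]
    w = max(1, int(round(_SMOOTH_S * record.sampling_rate)))
    return uniform_filter1d(x.astype(float), w)


def detect_r_peaks(record: ECGRecord, lead: str = "II") -> np.ndarray:
    """Sample indices of R peaks on the measurement lead."""
    x = _lead(record, lead)
    base = np.median(x)
    amp = np.max(x) - base
    if amp <= 0:
        return np.array([], dtype=int)
    fs = record.sampling_rate
    peaks, _ = find_peaks(
        x,
        height=base + 0.45 * amp,
        distance=int(0.28 * fs),
        prominence=0.35 * amp,
    )
    return peaks


def measure_rr_intervals(record: ECGRecord, lead: str = "II") -> np.ndarray:
    """Successive R-to-R intervals in seconds."""
    peaks = detect_r_peaks(record, lead)
    return np.diff(peaks) / record.sampling_rate


def rr_coefficient_of_variation(record: ECGRecord, lead: str = "II") -> float:
    rr = measure_rr_intervals(record, lead)
    if rr.size < 2 or rr.mean() <= 0:
        return float("nan")
    return float(rr.std(ddof=0) / rr.mean())


def measure_pr_interval(record: ECGRecord, lead: str = "II") -> float:
    """Median P-peak-to-R-peak interval (seconds), a PR-interval proxy.

    For each detected R peak the P wave is taken as the maximum of the
    smoothed lead in the window 0.07-0.36 s before the R peak; beats whose
    candidate P is below 0.05 mV over baseline are skipped (e.g. absent P
    waves in atrial fibrillation).  NaN when no beat yields a P wave.
    """
    x = _lead(record, lead)
    fs = record.sampling_rate
    base = np.median(x)
    out = []
    for r in detect_r_peaks(record, lead):
        lo, hi = r - int(0.36 * fs), r - int(0.07 * fs)
        if lo < 0:
            continue
        seg = x[lo:hi]
        if seg.size == 0:
            continue
        p = np.argmax(seg)
        if seg[p] - base < 0.05:
            continue
        out.append((r - (lo + p)) / fs)
    return float(np.median(out)) if out else float("nan")


def measure_qrs_widths(record: ECGRecord, lead: str = "II") -> np.ndarray:
    """Per-beat QRS duration (seconds) from the smoothed energy envelope.

    Around each R peak the squared deviation from baseline is box-smoothed
    (10 ms) and the QRS extent runs from the first to the last sample inside
    a +-120 ms window whose energy exceeds 2.5% of the peak energy (about
    16% in amplitude — below the Q/S lobes, above P waves and noise; the
    window stops short of the T wave).
    """
    x = _lead(record, lead)
    fs = record.sampling_rate
    base = np.median(x)
    energy = uniform_filter1d((x - base) ** 2, max(1, int(0.010 * fs)))
    half = int(0.12 * fs)
    widths = []
    for r in detect_r_peaks(record, lead):
        lo, hi = max(0, r - half), min(len(x), r + half)
        above = np.flatnonzero(energy[lo:hi] > 0.025 * energy[r])
        if above.size:
            widths.append((above[-1] - above[0] + 1) / fs)
    return np.asarray(widths)


def measure_st_level(record: ECGRecord, lead: str = "II") -> float:
    """Median ST-segment level (mV) relative to the isoelectric baseline.

    Averaged over 0.10-0.15 s after each R peak — inside the ST segment for
    both narrow and wide QRS complexes, ahead of the T wave.
    """
    x = _lead(record, lead)
    fs = record.sampling_rate
    base = np.median(x)
    lo_off, hi_off = int(0.10 * fs), int(0.15 * fs)
    levels = [
        np.mean(x[r + lo_off : r + hi_off]) - base
        for r in detect_r_peaks(record, lead)
        if r + hi_off <= len(x)
    ]
    return float(np.median(levels)) if levels else float("nan")


def qrs_amplitude_ratio_v1_v6(record: ECGRecord) -> float:
    """Peak-to-peak QRS amplitude ratio V1 / V6 (> 1 suggests RBBB-type axis)."""
    if "V1" not in record.lead_names or "V6" not in record.lead_names:
        return float("nan")
    fs = record.sampling_rate
    half = int(0.08 * fs)
    peaks = detect_r_peaks(record)
    pp = {}
    for name in ("V1", "V6"):
        y = record.signal[record.lead_names.index(name)]
        vals = [
            np.ptp(y[max(0, r - half) : r + half]) for r in peaks if r + half <= len(y)
        ]
        pp[name] = np.median(vals) if vals else np.nan
    return float(pp["V1"] / pp["V6"]) if pp["V6"] else float("nan")


def class_checks(record: ECGRecord) -> dict[str, bool]:
    """Evaluate every class-defining criterion this record's labels claim.

    Returns ``{acronym: passed}`` for each positive label.  Criteria:
    1dAVb PR > 0.2 s; AF RR coefficient of variation >= 0.15; LBBB/RBBB
    median QRS >= 0.12 s with V1/V6 amplitude ratio below/above 1; PAC a
    premature narrow beat (min RR <= 0.85 median); PVC a premature wide beat;
    STD/STE ST level <= -0.1 / >= +0.1 mV.
    """
    from .ecg_io import decode_labels

    labels = decode_labels(record.labels)
    rr = measure_rr_intervals(record)
    widths = measure_qrs_widths(record)
    results: dict[str, bool] = {}
    for name in labels:
        if name == "1dAVb":
            results[name] = measure_pr_interval(record) > 0.2
        elif name == "AF":
            results[name] = rr_coefficient_of_variation(record) >= 0.15
        elif name in ("LBBB", "RBBB"):
            ratio = qrs_amplitude_ratio_v1_v6(record)
            wide = widths.size > 0 and float(np.median(widths)) >= 0.12
            results[name] = wide and (ratio > 1 if name == "RBBB" else ratio < 1)
        elif name == "PAC":
            results[name] = rr.size >= 2 and rr.min() <= 0.85 * np.median(rr)
        elif name == "PVC":
            early = rr.size >= 2 and rr.min() <= 0.85 * np.median(rr)
            results[name] = early and widths.size > 0 and widths.max() >= 0.12
        elif name == "STD":
            results[name] = measure_st_level(record) <= -0.1
        elif name == "STE":
            results[name] = measure_st_level(record) >= 0.1
    return results


FEATURE_NAMES = (
    "pr_interval",
    "rr_cv",
    "rr_median",
    "qrs_median",
    "qrs_max",
    "rr_min_ratio",
    "st_level",
    "v1_v6_ratio",
)


def feature_vector(record: ECGRecord) -> np.ndarray:
    """Simple fiducial features (see FEATURE_NAMES) for baseline linear probes."""
    rr = measure_rr_intervals(record)
    widths = measure_qrs_widths(record)
    med_rr = float(np.median(rr)) if rr.size else np.nan
    return np.array(
        [
            measure_pr_interval(record),
            rr_coefficient_of_variation(record),
            med_rr,
            float(np.median(widths)) if widths.size else np.nan,
            float(np.max(widths)) if widths.size else np.nan,
            float(rr.min() / med_rr) if rr.size and med_rr else np.nan,
            measure_st_level(record),
            qrs_amplitude_ratio_v1_v6(record),
        ]
    )
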