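"""Seeded synthetic 12-lead ECG cohorts with class-conditioned morphology.

Each record is built from a train of PQRST complexes parameterized as
Gaussian bumps (plus a raised-cosine ST plateau) placed on a shared time
axis.  Three source trains — atrial (P), ventricular depolarization (QRS)
and repolarization (ST/T) — are projected to the standard 12 leads through a
fixed full-column-rank projection matrix, after which seeded Gaussian noise
and a slow sinusoidal baseline wander are added per lead.

Abnormality labels condition the morphology on the measurements that define
them clinically:

* ``1dAVb`` — PR interval drawn above 0.24 s (criterion: > 0.2 s);
* ``AF``    — absent P waves, fast rate, RR jitter with CV ~ 0.2;
* ``LBBB``/``RBBB`` — QRS duration >= 0.13 s with distinct fixed
  precordial weight vectors (V1-dominant for RBBB, V6-dominant for LBBB);
* ``PAC``/``PVC`` — randomly inserted premature beats, narrow vs wide;
* ``STD``/``STE`` — ST segment offset of about -0.2 / +0.3 mV.

The generator is a pure function of ``(config.seed, record_seed)``; its
output is validated by the independent estimators in
:mod:`cardiossm.measurements`, never by its own bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ecg_io import (
    FULL_CLASSES,
    OVERLAP_CLASSES,
    STANDARD_LEADS,
    ECGRecord,
    encode_labels,
)

__all__ = [
    "BeatTemplate",
    "SyntheticCohortConfig",
    "synth_beat",
    "synth_record",
    "synth_dataset",
    "LEAD_PROJECTION",
]

#: fixed 12 x 3 projection of the (P, QRS, ST/T) source trains onto leads.
#: Signs follow rough electrode geometry (aVR inverted, V1 QRS negative in
#: normal conduction); values are artifact-defined, full column rank.
LEAD_PROJECTION = np.array(
    [
        # P     QRS    ST/T
        [0.40, 0.60, 0.50],   # I
        [1.00, 1.00, 1.00],   # II
        [0.60, 0.50, 0.50],   # III
        [-0.70, -0.80, -0.75],  # aVR
        [0.20, 0.30, 0.25],   # aVL
        [0.80, 0.75, 0.75],   # aVF
        [0.30, -0.50, -0.30],  # V1
        [0.35, -0.30, 0.40],  # V2
        [0.40, 0.20, 0.60],   # V3
        [0.45, 0.70, 0.70],   # V4
        [0.40, 0.90, 0.80],   # V5
        [0.35, 0.80, 0.70],   # V6
    ]
)

#: QRS-column replacements giving the bundle-branch blocks their
#: lead-asymmetric amplitude signature
_QRS_WEIGHTS_RBBB = np.array(
    [0.50, 0.90, 0.45, -0.70, 0.25, 0.70, 1.30, 0.90, 0.50, 0.60, 0.50, 0.40]
)
_QRS_WEIGHTS_LBBB = np.array(
    [0.70, 1.00, 0.40, -0.80, 0.40, 0.70, -0.90, -0.60, 0.10, 0.60, 1.20, 1.30]
)


@dataclass
class BeatTemplate:
    """Gaussian-bump parameterization of one PQRST complex.

    Amplitudes in millivolts, widths (Gaussian sigma) and intervals in
    seconds.  ``pr_interval`` is the P-onset to QRS-onset time (P onset taken
    at 2 sigma before the P peak); ``qrs_duration`` spans Q through S.
    ``r2_amp``/``r2_pos`` add a second intra-QRS positive deflection (as a
    fraction of ``r_amp`` and of ``qrs_duration``): widely separated and
    tall for the rSR' pattern of right bundle branch block, close and
    merged for the notched broad R of left bundle branch block.
    """

    p_amp: float = 0.15
    p_width: float = 0.025
    q_amp: float = -0.10
    r_amp: float = 1.20
    s_amp: float = -0.25
    t_amp: float = 0.35
    t_width: float = 0.035
    pr_interval: float = 0.155
    qrs_duration: float = 0.08
    st_offset: float = 0.0
    rr_interval: float = 0.8
    r2_amp: float = 0.0      # second R wave, fraction of r_amp
    r2_pos: float = 0.75     # its center, fraction of qrs_duration past onset

    def __post_init__(self) -> None:
        if self.p_width <= 0 or self.t_width <= 0:
            raise ValueError("wave widths must be positive")
        if self.qrs_duration <= 0:
            raise ValueError("qrs_duration must be positive")
        if self.pr_interval < 0:
            raise ValueError("pr_interval must be >= 0")


@dataclass
class SyntheticCohortConfig:
    """Cohort-level generator settings.

    ``class_mix`` maps class acronym to marginal prevalence; labels are drawn
    independently per class (so co-occurrence happens at product rate) and
    redrawn when a physiologically incoherent combination comes up
    (AF with 1dAVb or PAC, LBBB with RBBB, STD with STE).
    """

    n_records: int = 500
    class_mix: dict = field(
        default_factory=lambda: {c: 0.2 for c in OVERLAP_CLASSES}
    )
    heart_rate_range: tuple[float, float] = (60.0, 90.0)
    noise_sd: float = 0.05          # mV, per-lead white noise
    sampling_rate: float = 500.0    # Hz
    length: int = 4096              # samples
    seed: int = 0

    def validate(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        for name, p in self.class_mix.items():
            if name not in FULL_CLASSES:
                raise ValueError(f"unknown class in class_mix: {name!r}")
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence for {name} outside [0, 1]: {p}")


# ---------------------------------------------------------------------------
# waveform assembly


def _add_gauss(train: np.ndarray, fs: float, center: float, amp: float,
               width: float) -> None:
    """Add one Gaussian bump in place, evaluated on a +-4 sigma window."""
    lo = max(0, int((center - 4 * width) * fs))
    hi = min(len(train), int((center + 4 * width) * fs) + 1)
    if hi <= lo:
        return
    t = np.arange(lo, hi) / fs
    train[lo:hi] += amp * np.exp(-0.5 * ((t - center) / width) ** 2)


def _add_plateau(train: np.ndarray, fs: float, start: float, stop: float,
                 amp: float, ramp: float = 0.02) -> None:
    """Raised-cosine-edged plateau from start to stop (seconds)."""
    lo = max(0, int((start - ramp) * fs))
    hi = min(len(train), int((stop + ramp) * fs) + 1)
    if hi <= lo or amp == 0:
        return
    t = np.arange(lo, hi) / fs
    env = np.ones_like(t)
    rising = t < start
    env[rising] = 0.5 * (1 + np.cos(np.pi * np.clip((start - t[rising]) / ramp, 0, 1)))
    falling = t > stop
    env[falling] = 0.5 * (1 + np.cos(np.pi * np.clip((t[falling] - stop) / ramp, 0, 1)))
    train[lo:hi] += amp * env


def _place_beat(trains: dict[str, np.ndarray], fs: float, r_time: float,
                tpl: BeatTemplate) -> None:
    """Place one beat's components, R peak at ``r_time`` seconds."""
    d = tpl.qrs_duration
    onset = r_time - 0.5 * d
    if tpl.p_amp != 0:
        p_center = onset - tpl.pr_interval + 2 * tpl.p_width
        _add_gauss(trains["p"], fs, p_center, tpl.p_amp, tpl.p_width)
    _add_gauss(trains["qrs"], fs, onset + 0.15 * d, tpl.q_amp, d / 8)
    _add_gauss(trains["qrs"], fs, onset + 0.50 * d, tpl.r_amp, d / 6)
    _add_gauss(trains["qrs"], fs, onset + 0.85 * d, tpl.s_amp, d / 8)
    if tpl.r2_amp != 0.0:
        _add_gauss(trains["qrs"], fs, onset + tpl.r2_pos * d,
                   tpl.r2_amp * tpl.r_amp, d / 9)
    qrs_end = onset + d
    _add_plateau(trains["t"], fs, qrs_end + 0.01, qrs_end + 0.14, tpl.st_offset)
    _add_gauss(trains["t"], fs, qrs_end + 0.20, tpl.t_amp, tpl.t_width)


def synth_beat(template: BeatTemplate, sampling_rate: float = 500.0) -> np.ndarray:
    """Single-beat single-channel waveform (sum of the three source trains).

    The beat is laid out with the QRS onset at ``pr_interval + 0.1`` s so the
    full P wave fits, over a span of one ``rr_interval`` beyond the onset.
    """
    fs = sampling_rate
    onset = template.pr_interval + 0.1
    n = int(round((onset + template.rr_interval) * fs))
    trains = {k: np.zeros(n) for k in ("p", "qrs", "t")}
    _place_beat(trains, fs, onset + 0.5 * template.qrs_duration, template)
    return trains["p"] + trains["qrs"] + trains["t"]


# ---------------------------------------------------------------------------
# class-conditioned record generation

_CONFLICTS = [{"AF", "1dAVb"}, {"AF", "PAC"}, {"LBBB", "RBBB"}, {"STD", "STE"}]


def _base_template(rng: np.random.Generator) -> BeatTemplate:
    return BeatTemplate(
        r_amp=rng.uniform(1.0, 1.4),
        pr_interval=rng.uniform(0.14, 0.17),
        qrs_duration=rng.uniform(0.07, 0.09),
    )


def synth_record(
    labels,
    config: SyntheticCohortConfig,
    record_seed: int,
) -> ECGRecord:
    """Generate one 12-lead record carrying the given abnormality labels.

    Deterministic given ``(config.seed, record_seed)``.
    """
    label_vec = encode_labels(labels)  # validates acronyms
    labels = set(labels)
    config.validate()
    rng = np.random.default_rng([abs(config.seed) % (2**31), record_seed % (2**31)])
    fs = config.sampling_rate
    duration = config.length / fs

    tpl = _base_template(rng)
    hr_lo, hr_hi = config.heart_rate_range
    rr_jitter_cv = 0.03
    if "1dAVb" in labels:
        tpl = replace(tpl, pr_interval=rng.uniform(0.26, 0.32))
    if "AF" in labels:
        hr_lo, hr_hi = 100.0, 140.0
        tpl = replace(tpl, p_amp=0.0)
    if "RBBB" in labels:
        # rsR' morphology: deep early S, tall late second R deflection
        tpl = replace(
            tpl,
            qrs_duration=rng.uniform(0.13, 0.16),
            q_amp=-0.40,
            s_amp=-0.70,
            r2_amp=0.85,
            r2_pos=0.95,
        )
    elif "LBBB" in labels:
        # broad notched R: second positive deflection merged with the R wave
        tpl = replace(
            tpl,
            qrs_duration=rng.uniform(0.13, 0.16),
            q_amp=-0.40,
            s_amp=-0.55,
            r2_amp=0.60,
            r2_pos=0.68,
        )
    if "STD" in labels:
        tpl = replace(tpl, st_offset=-rng.uniform(0.15, 0.25))
    if "STE" in labels:
        tpl = replace(tpl, st_offset=rng.uniform(0.25, 0.35))

    rr_base = 60.0 / rng.uniform(hr_lo, hr_hi)

    # build the R-peak schedule, marking premature beats for PAC / PVC; for
    # AF the schedule is redrawn until its RR coefficient of variation gives
    # comfortable margin over the 0.15 class criterion
    for _ in range(100):
        r_times: list[float] = []
        premature: list[bool] = []
        rr_list: list[float] = []
        t = 0.35 + rng.uniform(0.0, 0.2)
        ectopic_rate = 0.18
        while t < duration + 0.4:
            r_times.append(t)
            if "AF" in labels:
                rr = rr_base * rng.uniform(0.65, 1.55)
            else:
                rr = rr_base * (1.0 + rr_jitter_cv * rng.standard_normal())
            is_premature = False
            if ("PAC" in labels or "PVC" in labels) and len(r_times) >= 2:
                if rng.random() < ectopic_rate:
                    rr = rr_base * rng.uniform(0.55, 0.70)
                    is_premature = True
            premature.append(is_premature)
            rr = max(rr, 0.35)
            rr_list.append(rr)
            t += rr
        if "AF" not in labels:
            break
        rr_arr = np.array(rr_list[:-1])
        if rr_arr.std() / rr_arr.mean() >= 0.18:
            break
    # premature flag i marks the *interval* before beat i+1; guarantee one
    if ("PAC" in labels or "PVC" in labels) and not any(premature[:-1]):
        k = int(rng.integers(1, max(2, len(r_times) - 1)))
        r_times[k:] = [x - 0.35 * rr_base for x in r_times[k:]]
        premature[k - 1] = True

    trains = {k: np.zeros(config.length) for k in ("p", "qrs", "t")}
    prev_was_premature = False
    for i, r_t in enumerate(r_times):
        beat_tpl = replace(tpl, r_amp=tpl.r_amp * rng.uniform(0.95, 1.05))
        if prev_was_premature and "PVC" in labels:
            beat_tpl = replace(
                beat_tpl,
                qrs_duration=rng.uniform(0.14, 0.17),
                p_amp=0.0,
                r_amp=tpl.r_amp * 1.25,
                q_amp=-0.45,
                s_amp=-0.60,
            )
        _place_beat(trains, fs, r_t, beat_tpl)
        prev_was_premature = premature[i] if i < len(premature) else False

    if "AF" in labels:  # coarse fibrillatory undulation replacing P waves
        tt = np.arange(config.length) / fs
        trains["p"] += 0.03 * np.sin(
            2 * np.pi * rng.uniform(5.0, 7.0) * tt + rng.uniform(0, 2 * np.pi)
        )

    projection = LEAD_PROJECTION.copy()
    if "RBBB" in labels:
        projection[:, 1] = _QRS_WEIGHTS_RBBB
    elif "LBBB" in labels:
        projection[:, 1] = _QRS_WEIGHTS_LBBB
    # inter-patient electrical-axis variability: per-record multiplicative
    # jitter of every projection weight (sign-preserving, bounded so the
    # class-defining V1/V6 asymmetry cannot flip)
    projection = projection * rng.uniform(0.88, 1.15, size=projection.shape)

    source = np.vstack([trains["p"], trains["qrs"], trains["t"]])
    signal = projection @ source
    signal += rng.normal(0.0, config.noise_sd, signal.shape)
    wander_f = rng.uniform(0.15, 0.35)
    tt = np.arange(config.length) / fs
    phases = rng.uniform(0, 2 * np.pi, 12)
    amps = rng.uniform(0.02, 0.05, 12)
    signal += amps[:, None] * np.sin(2 * np.pi * wander_f * tt + phases[:, None])

    return ECGRecord(
        signal=signal,
        sampling_rate=fs,
        lead_names=STANDARD_LEADS,
        labels=label_vec,
        record_id=f"syn-{record_seed:05d}",
    )


def _draw_labels(rng: np.random.Generator, class_mix: dict) -> list[str]:
    names = [c for c in FULL_CLASSES if c in class_mix]
    probs = np.array([class_mix[c] for c in names])
    for _ in range(1000):
        hit = rng.random(len(names)) < probs
        chosen = {n for n, h in zip(names, hit) if h}
        if not any(conflict <= chosen for conflict in _CONFLICTS):
            return [n for n in names if n in chosen]
    raise RuntimeError("could not draw a conflict-free label set")


def synth_dataset(
    config: SyntheticCohortConfig,
) -> tuple[list[ECGRecord], pd.DataFrame]:
    """Generate a full cohort plus its label manifest.

    Record ``i`` uses ``record_seed=i``; demographics (age, sex) are drawn
    from the cohort-level stream.  Pure function of ``config``.
    """
    config.validate()
    rng = np.random.default_rng(abs(config.seed) % (2**31))
    records = []
    for i in range(config.n_records):
        labels = _draw_labels(rng, config.class_mix)
        rec = synth_record(labels, config, record_seed=i)
        rec.age = float(np.clip(np.round(rng.normal(60, 15)), 18, 95))
        rec.sex = "F" if rng.random() < 0.5 else "M"
        records.append(rec)
    manifest = pd.DataFrame(
        {
            "record_id": [r.record_id for r in records],
            "labels": [
                ";".join(n for n in FULL_CLASSES if r.labels[FULL_CLASSES.index(n)])
                for r in records
            ],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
        }
    )
    return records, manifest
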