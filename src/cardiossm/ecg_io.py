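"""Reading, shaping and labeling multi-lead ECG records.

Supported on-disk forms:

* delimited numeric matrices (CSV/TSV; orientation auto-detected, longer
  axis = time),
* a single-file HDF5 container with datasets ``signal``, ``labels``,
  ``lead_names``, ``fs``,
* minimal WFDB-style header/signal pairs (text ``.hea`` plus 16-bit ``.dat``),

together with a label-manifest CSV (``record_id, labels, age, sex`` with
semicolon-joined class acronyms).

The class vocabulary is the eight-abnormality set used throughout the
package — first-degree AV block, atrial fibrillation, left/right bundle
branch block, premature atrial/ventricular contractions and ST
depression/elevation — with the four-class subset shared by typical
out-of-sample telehealth cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.signal import resample_poly

__all__ = [
    "FULL_CLASSES",
    "OVERLAP_CLASSES",
    "STANDARD_LEADS",
    "ECGRecord",
    "read_record",
    "write_record",
    "resample_to",
    "standardize_length",
    "encode_labels",
    "decode_labels",
    "select_leads",
    "save_cohort",
    "load_cohort",
    "write_manifest",
    "read_manifest",
]

#: full 8-class vocabulary, in canonical order
FULL_CLASSES: tuple[str, ...] = (
    "1dAVb", "AF", "LBBB", "RBBB", "PAC", "PVC", "STD", "STE",
)
#: the 4 classes shared with the out-of-sample cohort
OVERLAP_CLASSES: tuple[str, ...] = ("1dAVb", "AF", "LBBB", "RBBB")

#: standard 12-lead order
STANDARD_LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: conventional fixed record shape: 500 Hz, 4096 samples (~8.2 s)
DEFAULT_FS = 500.0
DEFAULT_LENGTH = 4096


@dataclass
class ECGRecord:
    """One multi-lead ECG: ``signal`` is ``n_leads x n_samples`` in millivolts."""

    signal: np.ndarray
    sampling_rate: float = DEFAULT_FS
    lead_names: tuple[str, ...] = STANDARD_LEADS
    labels: np.ndarray = field(default_factory=lambda: np.zeros(len(FULL_CLASSES), dtype=np.int8))
    record_id: str = ""
    age: float | None = None
    sex: str | None = None
    padded: bool = False
    excluded: bool = False

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        self.lead_names = tuple(self.lead_names)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.signal.shape[0] != len(self.lead_names):
            raise ValueError(
                f"{self.signal.shape[0]} signal rows but "
                f"{len(self.lead_names)} lead names"
            )
        if self.signal.size and not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite samples")
        if self.n_samples == 0:
            # a record with only empty sample entries is flagged for exclusion
            self.excluded = True

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Seconds; sample n sits at time n / sampling_rate."""
        return self.n_samples / self.sampling_rate

    def replace(self, **changes) -> "ECGRecord":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# label handling


def encode_labels(names, vocab: tuple[str, ...] = FULL_CLASSES) -> np.ndarray:
    """Multi-hot encode class acronyms; several simultaneous labels allowed."""
    vec = np.zeros(len(vocab), dtype=np.int8)
    for name in names:
        if name not in vocab:
            raise ValueError(f"unknown class acronym: {name!r}")
        vec[vocab.index(name)] = 1
    return vec


def decode_labels(vec: np.ndarray, vocab: tuple[str, ...] = FULL_CLASSES) -> list[str]:
    return [vocab[i] for i in np.flatnonzero(np.asarray(vec))]


# ---------------------------------------------------------------------------
# readers / writers


def _read_delimited(path: Path) -> ECGRecord:
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    first = path.read_text().splitlines()[0] if path.stat().st_size else ""
    try:
        float(first.split(sep)[0])
        has_header = False
    except ValueError:
        has_header = True
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    mat = df.to_numpy(dtype=float)
    names: tuple[str, ...] | None = tuple(map(str, df.columns)) if has_header else None

    # orientation: the longer axis is time
    if mat.shape[0] > mat.shape[1]:
        mat = mat.T  # rows were samples -> now leads x samples
    elif names is not None and len(names) == mat.shape[1]:
        # header names label columns; after no transpose they label samples,
        # which only makes sense if columns were leads (square-ish case)
        pass
    if names is not None and len(names) != mat.shape[0]:
        names = None  # header did not name leads after orientation fix

    if names is not None:
        for n in names:
            if n not in STANDARD_LEADS:
                raise ValueError(f"unknown lead name in header: {n!r}")
        order = [names.index(n) for n in STANDARD_LEADS if n in names]
        mat = mat[order]
        names = tuple(n for n in STANDARD_LEADS if n in names)
    else:
        names = STANDARD_LEADS[: mat.shape[0]] if mat.shape[0] <= 12 else tuple(
            f"ch{i}" for i in range(mat.shape[0])
        )
    return ECGRecord(signal=mat, lead_names=names, record_id=path.stem)


def _write_delimited(record: ECGRecord, path: Path) -> None:
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.DataFrame(record.signal.T, columns=list(record.lead_names))
    df.to_csv(path, sep=sep, index=False)


def _read_container(path: Path) -> ECGRecord:
    with h5py.File(path, "r") as f:
        names = tuple(s.decode() if isinstance(s, bytes) else str(s) for s in f["lead_names"][()])
        age = f.attrs.get("age", np.nan)
        sex = f.attrs.get("sex", "")
        return ECGRecord(
            signal=f["signal"][()],
            sampling_rate=float(f["fs"][()]),
            lead_names=names,
            labels=f["labels"][()],
            record_id=str(f.attrs.get("record_id", path.stem)),
            age=None if np.isnan(age) else float(age),
            sex=str(sex) or None,
            padded=bool(f.attrs.get("padded", False)),
        )


def _write_container(record: ECGRecord, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=record.signal)
        f.create_dataset("labels", data=record.labels)
        f.create_dataset(
            "lead_names", data=np.array([n.encode() for n in record.lead_names])
        )
        f.create_dataset("fs", data=record.sampling_rate)
        f.attrs["record_id"] = record.record_id
        f.attrs["age"] = np.nan if record.age is None else record.age
        f.attrs["sex"] = record.sex or ""
        f.attrs["padded"] = record.padded


_WFDB_GAIN = 1000.0  # ADC units per millivolt in our writer


def _read_wfdb(path: Path) -> ECGRecord:
    """Minimal WFDB-style reader: text header + interleaved int16 samples."""
    lines = [
        ln for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    try:
        name, n_sig, fs, n_samples = lines[0].split()[:4]
        n_sig, fs, n_samples = int(n_sig), float(fs), int(n_samples)
    except (ValueError, IndexError) as exc:
        raise ValueError(f"unparseable WFDB header line: {lines[0]!r}") from exc
    dat_file, gains, leads = None, [], []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        if len(tok) < 3 or tok[1] != "16":
            raise ValueError(f"unsupported WFDB signal line (format-16 only): {ln!r}")
        dat_file = tok[0]
        gains.append(float(tok[2].split("/")[0].split("(")[0]))
        leads.append(tok[-1])
    for lead in leads:
        if lead not in STANDARD_LEADS:
            raise ValueError(f"unknown lead name: {lead!r}")
    raw = np.fromfile(path.parent / dat_file, dtype="<i2")
    sig = raw.reshape(n_samples, n_sig).T / np.array(gains)[:, None]
    order = [leads.index(n) for n in STANDARD_LEADS if n in leads]
    return ECGRecord(
        signal=sig[order],
        sampling_rate=fs,
        lead_names=tuple(n for n in STANDARD_LEADS if n in leads),
        record_id=name,
    )


def _write_wfdb(record: ECGRecord, path: Path) -> None:
    dat = path.with_suffix(".dat")
    header = [f"{record.record_id or path.stem} {record.n_leads} "
              f"{record.sampling_rate:g} {record.n_samples}"]
    for lead in record.lead_names:
        header.append(f"{dat.name} 16 {_WFDB_GAIN:g}(0)/mV 16 0 0 0 0 {lead}")
    path.write_text("\n".join(header) + "\n")
    q = np.clip(np.round(record.signal * _WFDB_GAIN), -32768, 32767)
    q.T.astype("<i2").tofile(dat)


_FORMATS = {"delimited": (_read_delimited, _write_delimited),
            "container": (_read_container, _write_container),
            "wfdb": (_read_wfdb, _write_wfdb)}


def _infer_format(path: Path) -> str:
    ext = path.suffix.lower()
    if ext in {".csv", ".tsv", ".txt"}:
        return "delimited"
    if ext in {".h5", ".hdf5", ".hdf"}:
        return "container"
    if ext == ".hea":
        return "wfdb"
    raise ValueError(f"cannot infer record format from extension {ext!r}")


def read_record(path, fmt: str | None = None) -> ECGRecord:
    """Read one ECG record; format inferred from the extension when not given.

    Leads are reordered to standard 12-lead order whenever names are present;
    records with only empty sample entries come back with ``excluded=True``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {sorted(_FORMATS)}")
    return _FORMATS[fmt][0](path)


def write_record(record: ECGRecord, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or _infer_format(path)
    _FORMATS[fmt][1](record, path)


# ---------------------------------------------------------------------------
# shaping


def resample_to(record: ECGRecord, target_rate: float) -> ECGRecord:
    """Polyphase-resample all leads; new length = round(n * target/source)."""
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == record.sampling_rate:
        return record.replace(signal=record.signal.copy())
    frac = Fraction(target_rate / record.sampling_rate).limit_denominator(1000)
    out = resample_poly(record.signal, frac.numerator, frac.denominator, axis=1)
    n_target = int(round(record.n_samples * target_rate / record.sampling_rate))
    if out.shape[1] > n_target:
        out = out[:, :n_target]
    elif out.shape[1] < n_target:
        out = np.pad(out, ((0, 0), (0, n_target - out.shape[1])), mode="edge")
    return record.replace(signal=out, sampling_rate=float(target_rate))


def standardize_length(record: ECGRecord, target_length: int = DEFAULT_LENGTH) -> ECGRecord:
    """Truncate to the first ``target_length`` samples, or zero-pad and flag."""
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    n = record.n_samples
    if n == target_length:
        return record
    if n > target_length:
        return record.replace(signal=record.signal[:, :target_length].copy())
    pad = np.zeros((record.n_leads, target_length - n))
    return record.replace(signal=np.hstack([record.signal, pad]), padded=True)


def select_leads(record: ECGRecord, names) -> ECGRecord:
    """Sub-record with only the requested leads, in the requested order."""
    names = list(names)
    for n in names:
        if n not in record.lead_names:
            raise ValueError(f"lead {n!r} not present in record {record.record_id!r}")
    idx = [record.lead_names.index(n) for n in names]
    return record.replace(signal=record.signal[idx].copy(), lead_names=tuple(names))


# ---------------------------------------------------------------------------
# cohort container and manifest


def save_cohort(records: list[ECGRecord], path) -> None:
    """Write a homogeneous cohort to one HDF5 file (signals n x leads x L)."""
    if not records:
        raise ValueError("empty cohort")
    shapes = {r.signal.shape for r in records}
    if len(shapes) > 1:
        raise ValueError(f"heterogeneous record shapes: {sorted(shapes)}")
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "signals", data=np.stack([r.signal for r in records]).astype(np.float32)
        )
        f.create_dataset("labels", data=np.stack([r.labels for r in records]))
        f.create_dataset(
            "record_ids",
            data=np.array([r.record_id.encode() for r in records]),
        )
        f.create_dataset(
            "lead_names",
            data=np.array([n.encode() for n in records[0].lead_names]),
        )
        f.create_dataset("fs", data=records[0].sampling_rate)


def load_cohort(path) -> list[ECGRecord]:
    with h5py.File(path, "r") as f:
        signals = f["signals"][()]
        labels = f["labels"][()]
        ids = [s.decode() for s in f["record_ids"][()]]
        leads = tuple(s.decode() for s in f["lead_names"][()])
        fs = float(f["fs"][()])
    return [
        ECGRecord(signal=signals[i], sampling_rate=fs, lead_names=leads,
                  labels=labels[i], record_id=ids[i])
        for i in range(signals.shape[0])
    ]


def write_manifest(records: list[ECGRecord], path) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "record_id": [r.record_id for r in records],
            "labels": [";".join(decode_labels(r.labels)) for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
        }
    )
    df.to_csv(path, index=False)
    return df


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"record_id": str}, keep_default_na=False)
    df["labels"] = df["labels"].fillna("")
    return df
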