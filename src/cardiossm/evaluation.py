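"""Multi-label evaluation: confusion metrics, AUROC/AUPRC, weighted
averaging, class-subset reports, and the lead-ablation robustness protocol.

Conventions (documented design choices):

* AUROC uses the rank / Mann-Whitney formulation with ties credited 1/2;
* AUPRC is average precision (step-wise integral of precision over recall);
* per-class accuracy is one-vs-rest at the binarization threshold;
* "weighted average" weights each class by its positive-label support;
* an "emptied" lead is a lead set to all zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .ecg_io import FULL_CLASSES, ECGRecord
from .trainer import records_to_arrays

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "RobustnessResult",
    "confusion_counts",
    "classification_metrics",
    "auroc",
    "auprc",
    "weighted_average",
    "evaluate",
    "mask_leads",
    "robustness_curve",
]


@dataclass
class ConfusionCounts:
    """Per-class TP/TN/FP/FN over records; arrays of shape (n_classes,)."""

    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.tp + self.tn + self.fp + self.fn


def _check_binary(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x)
    if not np.isin(x, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 entries")
    return x.astype(np.int64)


def confusion_counts(pred: np.ndarray, labels: np.ndarray) -> ConfusionCounts:
    """Column-wise confusion counts for multi-hot predictions vs labels."""
    pred = _check_binary(pred, "pred")
    labels = _check_binary(labels, "labels")
    if pred.shape != labels.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs labels {labels.shape}")
    pred = np.atleast_2d(pred)
    labels = np.atleast_2d(labels)
    tp = ((pred == 1) & (labels == 1)).sum(axis=0)
    tn = ((pred == 0) & (labels == 0)).sum(axis=0)
    fp = ((pred == 1) & (labels == 0)).sum(axis=0)
    fn = ((pred == 0) & (labels == 1)).sum(axis=0)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def classification_metrics(counts: ConfusionCounts):
    """Accuracy, precision, recall and F1 per class.

    accuracy = (TP+TN)/total, recall = TP/(TP+FN), precision = TP/(TP+FP),
    F1 = 2 PR/(P+R); degenerate 0/0 ratios are defined as 0.
    """
    if np.any(counts.total == 0):
        raise ValueError("zero total count for at least one class")

    def _safe(num, den):
        den = np.asarray(den, dtype=float)
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)

    accuracy = (counts.tp + counts.tn) / counts.total
    recall = _safe(counts.tp, counts.tp + counts.fn)
    precision = _safe(counts.tp, counts.tp + counts.fp)
    f1 = _safe(2 * precision * recall, precision + recall)
    return accuracy, precision, recall, f1


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability a random positive outscores a random negative (ties = 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels, "labels")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average precision: mean of precision-at-rank over the positives,
    ranked by descending score (stable order)."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels, "labels")
    if labels.sum() == 0:
        raise ValueError("AUPRC undefined: no positive labels")
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    precision_at = np.cumsum(y) / np.arange(1, y.size + 1)
    return float(precision_at[y == 1].mean())


def weighted_average(values, supports) -> float:
    """Support-weighted mean: sum(value * support) / sum(support)."""
    values = np.asarray(values, dtype=float)
    supports = np.asarray(supports, dtype=float)
    if np.any(supports < 0):
        raise ValueError("supports must be >= 0")
    if supports.sum() <= 0:
        raise ValueError("total support is zero")
    return float(np.sum(values * supports) / supports.sum())


@dataclass
class MetricsReport:
    """Per-class and support-weighted metrics for one evaluation pass."""

    class_names: tuple[str, ...]
    f1: np.ndarray
    auroc: np.ndarray
    auprc: np.ndarray
    accuracy: np.ndarray
    support: np.ndarray
    weighted: dict
    n_records: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "class": list(self.class_names),
                "f1": self.f1,
                "auroc": self.auroc,
                "auprc": self.auprc,
                "accuracy": self.accuracy,
                "support": self.support,
            }
        )
        df.loc[len(df)] = [
            "weighted_average",
            self.weighted["f1"],
            self.weighted["auroc"],
            self.weighted["auprc"],
            self.weighted["accuracy"],
            int(self.support.sum()),
        ]
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _scores_from(model, x: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(x))
    return np.asarray(model(x))


def evaluate(
    model,
    dataset,
    threshold: float = 0.5,
    class_subset=None,
    class_names: tuple[str, ...] = FULL_CLASSES,
    batch_size: int = 64,
) -> MetricsReport:
    """Score a model on a labeled dataset and compile a metrics report.

    ``model`` is anything with ``predict_proba(X) -> (n, n_classes)`` (or a
    plain callable); ``dataset`` is a record list or an ``(X, Y)`` pair.
    ``class_subset`` restricts the report (and the weighted averages) to the
    named classes.  AUROC/AUPRC for a class that is single-valued in the
    dataset are reported as NaN and excluded from the weighted averages.
    """
    if isinstance(dataset, tuple):
        x, y = dataset
    else:
        if len(dataset) == 0:
            raise ValueError("cannot evaluate on an empty dataset")
        x, y = records_to_arrays(dataset)
    y = np.atleast_2d(np.asarray(y))
    scores = _scores_from(model, x)
    if class_subset is not None:
        for name in class_subset:
            if name not in class_names:
                raise ValueError(f"unknown class in subset: {name!r}")
        cols = [class_names.index(n) for n in class_subset]
        scores, y = scores[:, cols], y[:, cols]
        class_names = tuple(class_subset)

    pred = (scores >= threshold).astype(np.int8)
    counts = confusion_counts(pred, y)
    accuracy, _, _, f1 = classification_metrics(counts)
    n_classes = y.shape[1]
    roc = np.full(n_classes, np.nan)
    prc = np.full(n_classes, np.nan)
    for j in range(n_classes):
        col = y[:, j]
        if 0 < col.sum() < col.size:
            roc[j] = auroc(scores[:, j], col)
        if col.sum() > 0:
            prc[j] = auprc(scores[:, j], col)
    support = y.sum(axis=0)

    def _wavg(vals):
        ok = np.isfinite(vals) & (support > 0)
        if not ok.any():
            return float("nan")
        return weighted_average(vals[ok], support[ok])

    weighted = {
        "f1": _wavg(f1.astype(float)),
        "auroc": _wavg(roc),
        "auprc": _wavg(prc),
        "accuracy": _wavg(accuracy.astype(float)),
    }
    return MetricsReport(
        class_names=class_names,
        f1=f1,
        auroc=roc,
        auprc=prc,
        accuracy=accuracy,
        support=support,
        weighted=weighted,
        n_records=y.shape[0],
    )


def mask_leads(record: ECGRecord, k: int, seed: int) -> ECGRecord:
    """Zero exactly ``k`` distinct leads chosen uniformly under ``seed``."""
    if not 0 <= k <= record.n_leads:
        raise ValueError(f"k must be in [0, {record.n_leads}], got {k}")
    sig = record.signal.copy()
    rows = np.random.default_rng(seed).choice(record.n_leads, size=k, replace=False)
    sig[rows] = 0.0
    return record.replace(signal=sig)


def _mask_array(x: np.ndarray, k: int, rng: np.random.Generator,
                per_record: bool) -> np.ndarray:
    out = x.copy()
    n_leads = x.shape[1]
    if per_record:
        for i in range(x.shape[0]):
            out[i, rng.choice(n_leads, size=k, replace=False)] = 0.0
    else:
        out[:, rng.choice(n_leads, size=k, replace=False)] = 0.0
    return out


@dataclass
class RobustnessResult:
    """Mean weighted metrics per masking level k (k=0 baseline included)."""

    ks: tuple[int, ...]
    f1: np.ndarray
    auroc: np.ndarray
    auprc: np.ndarray
    accuracy: np.ndarray
    repeats: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "masked_leads": list(self.ks),
                "f1": self.f1,
                "auroc": self.auroc,
                "auprc": self.auprc,
                "accuracy": self.accuracy,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def robustness_curve(
    model,
    dataset,
    schedule=(2, 4, 6, 8, 10),
    repeats: int = 3,
    seed: int = 0,
    threshold: float = 0.5,
    class_subset=None,
    class_names: tuple[str, ...] = FULL_CLASSES,
    per_record: bool = True,
) -> RobustnessResult:
    """Weighted metrics as an increasing number of leads is zeroed at inference.

    For each k in the schedule the dataset is re-masked ``repeats`` times
    (masks re-drawn per record by default) and the mean weighted metrics are
    reported; k=0 is always included as the unmasked baseline.
    """
    if isinstance(dataset, tuple):
        x, y = dataset
    else:
        x, y = records_to_arrays(dataset)
    n_leads = x.shape[1]
    for k in schedule:
        if not 0 <= k <= n_leads:
            raise ValueError(f"schedule value {k} invalid for {n_leads} leads")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    ks = tuple(sorted({0, *schedule}))
    rng = np.random.default_rng(seed)
    rows = {m: [] for m in ("f1", "auroc", "auprc", "accuracy")}
    for k in ks:
        reps = 1 if k == 0 else repeats
        vals = {m: [] for m in rows}
        for _ in range(reps):
            xm = x if k == 0 else _mask_array(x, k, rng, per_record)
            rep = evaluate((lambda a: _scores_from(model, a)), (xm, y),
                           threshold=threshold, class_subset=class_subset,
                           class_names=class_names)
            for m in vals:
                vals[m].append(rep.weighted[m])
        for m in rows:
            rows[m].append(float(np.mean(vals[m])))
    return RobustnessResult(
        ks=ks,
        f1=np.array(rows["f1"]),
        auroc=np.array(rows["auroc"]),
        auprc=np.array(rows["auprc"]),
        accuracy=np.array(rows["accuracy"]),
        repeats=repeats,
        seed=seed,
    )
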