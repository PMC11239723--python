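"""Training loop: AdamW + cosine-annealed learning rate + binary cross-entropy.

The recipe is the one the classifier is designed around: AdamW with a peak
learning rate of 1e-3 annealed to ``lr_min`` over exactly ``epochs`` epochs
by the closed-form cosine schedule (no early stopping), batch size 32,
unweighted multi-label BCE.  Per-epoch train/validation loss, per-entry
accuracy and the learning rate are recorded so the full history can be
written as CSV.

"Accuracy" here is per-entry accuracy of the thresholded multi-hot output
(each record x class cell counted separately), the natural reading for a
multi-label problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecg_io import ECGRecord
from .network import S4DClassifier, sigmoid

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "bce_loss",
    "cosine_annealed_lr",
    "split_train_val",
    "records_to_arrays",
    "train",
    "AdamW",
]

_P_CLAMP = 1e-7


@dataclass
class TrainingConfig:
    learning_rate: float = 0.001
    epochs: int = 200
    batch_size: int = 32
    weight_decay: float = 0.01
    lr_min: float = 0.0
    val_fraction: float = 0.15
    grad_clip: float | None = None   # max global grad norm; None = no clipping
    threshold: float = 0.5           # binarization for the accuracy trace
    #: start the decoder bias at the per-class prior log-odds so early steps
    #: go into feature learning rather than matching base rates
    prior_bias_init: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass
class TrainingHistory:
    epoch: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": self.epoch,
                "train_loss": self.train_loss,
                "train_acc": self.train_acc,
                "val_loss": self.val_loss,
                "val_acc": self.val_acc,
                "lr": self.lr,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def bce_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy over all entries, probabilities clamped
    to [1e-7, 1 - 1e-7] for finiteness."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: probabilities {p.shape} vs labels {y.shape}")
    p = np.clip(p, _P_CLAMP, 1.0 - _P_CLAMP)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def cosine_annealed_lr(epoch: int, total_epochs: int, lr_max: float,
                       lr_min: float = 0.0) -> float:
    """lr_min + (lr_max - lr_min) * (1 + cos(pi * epoch / total)) / 2."""
    if not 0 <= epoch <= total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {total_epochs}]")
    return lr_min + (lr_max - lr_min) * (1.0 + np.cos(np.pi * epoch / total_epochs)) / 2.0


def split_train_val(dataset, val_fraction: float, seed: int):
    """Disjoint, exhaustive, seeded split, stratified by label combination.

    Records sharing the same multi-hot label vector are split together so
    rare combinations land on both sides whenever their count permits.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("cannot split an empty dataset")
    if not 0 < val_fraction < 1:
        raise ValueError("val_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    groups: dict[tuple, list[int]] = {}
    for i, rec in enumerate(dataset):
        key = tuple(np.asarray(rec.labels).tolist()) if isinstance(rec, ECGRecord) else ()
        groups.setdefault(key, []).append(i)
    val_idx: list[int] = []
    for key in sorted(groups):
        idx = np.array(groups[key])
        rng.shuffle(idx)
        n_val = int(round(val_fraction * len(idx)))
        val_idx.extend(idx[:n_val].tolist())
    # guarantee both sides non-empty
    all_idx = set(range(len(dataset)))
    if not val_idx:
        val_idx = [int(rng.integers(len(dataset)))]
    if set(val_idx) == all_idx:
        val_idx = val_idx[:-1]
    val_set = sorted(val_idx)
    train_set = sorted(all_idx - set(val_set))
    return [dataset[i] for i in train_set], [dataset[i] for i in val_set]


def records_to_arrays(records, dtype=np.float32):
    """Stack a homogeneous record list into (X, Y) arrays; reject ragged input."""
    records = list(records)
    shapes = {}
    for r in records:
        shapes.setdefault(r.signal.shape, []).append(r.record_id)
    if len(shapes) > 1:
        smallest = min(shapes.items(), key=lambda kv: len(kv[1]))
        raise ValueError(
            "heterogeneous record shapes; offending records: "
            + ", ".join(smallest[1][:10])
        )
    x = np.stack([r.signal for r in records]).astype(dtype)
    y = np.stack([r.labels for r in records]).astype(np.int8)
    return x, y


class AdamW:
    """AdamW with decoupled weight decay (betas 0.9/0.999, eps 1e-8)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.01):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self._v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad.astype(np.float64)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            wd = self.weight_decay if getattr(p, "decay", True) else 0.0
            p.data -= (self.lr * (update + wd * p.data)).astype(p.data.dtype)


def _epoch_eval(model, x, y, batch_size, threshold):
    p = model.predict_proba(x, batch_size=batch_size)
    return bce_loss(p, y), float(np.mean((p >= threshold) == (y > 0)))


def train(
    model: S4DClassifier,
    dataset,
    config: TrainingConfig,
    val_dataset=None,
) -> tuple[S4DClassifier, TrainingHistory]:
    """Train in place for exactly ``config.epochs`` epochs (no early stopping).

    ``dataset`` is a list of ECGRecords (or an (X, Y) pair).  When no
    explicit validation set is given, a stratified ``val_fraction`` split is
    carved out first.  Reproducible given ``config.seed`` on one device.
    """
    config.validate()
    if isinstance(dataset, tuple):
        x_train, y_train = dataset
        x_val, y_val = val_dataset if val_dataset is not None else (x_train, y_train)
    else:
        if val_dataset is None:
            train_recs, val_recs = split_train_val(
                dataset, config.val_fraction, config.seed
            )
        else:
            train_recs, val_recs = list(dataset), list(val_dataset)
        x_train, y_train = records_to_arrays(train_recs, dtype=model.dtype)
        x_val, y_val = records_to_arrays(val_recs, dtype=model.dtype)

    rng = np.random.default_rng(config.seed)
    model.reseed_dropout(rng.integers(2**31))
    if config.prior_bias_init and hasattr(model, "decoder"):
        prior = np.clip(y_train.mean(axis=0), 1e-3, 1 - 1e-3)
        model.decoder.b.data = np.log(prior / (1 - prior)).astype(model.dtype)
    opt = AdamW(
        model.parameters(),
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    history = TrainingHistory()
    n = x_train.shape[0]
    for epoch in range(config.epochs):
        lr = cosine_annealed_lr(epoch, config.epochs, config.learning_rate,
                                config.lr_min)
        opt.lr = lr
        order = rng.permutation(n)
        losses, accs, weights = [], [], []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = x_train[idx]
            yb = y_train[idx].astype(model.dtype)
            logits = model.forward(xb, training=True)
            p = sigmoid(logits)
            losses.append(bce_loss(p, yb))
            accs.append(float(np.mean((p >= config.threshold) == (yb > 0))))
            weights.append(len(idx))
            model.zero_grad()
            dlogits = (p - yb) / p.size
            model.backward(dlogits)
            if config.grad_clip is not None:
                norm = np.sqrt(sum(float((q.grad**2).sum()) for q in model.parameters()))
                if norm > config.grad_clip:
                    for q in model.parameters():
                        q.grad *= config.grad_clip / norm
            opt.step()
        val_loss, val_acc = _epoch_eval(model, x_val, y_val, config.batch_size,
                                        config.threshold)
        history.epoch.append(epoch)
        history.train_loss.append(float(np.average(losses, weights=weights)))
        history.train_acc.append(float(np.average(accs, weights=weights)))
        history.val_loss.append(val_loss)
        history.val_acc.append(val_acc)
        history.lr.append(lr)
    return model, history
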