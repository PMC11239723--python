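"""Train a small classifier on a synthetic cohort and report its metrics.

A reduced version of the full study (2 layers, model dim 16, 2048 samples,
25 epochs, 400 records) so it runs in a couple of minutes on one CPU.  The
printed report lists per-class F1/AUROC/AUPRC/accuracy with positive-label
supports and the support-weighted averages — the same table structure the
full-scale evaluation produces.  Expect strong scores for the
amplitude-signature classes (LBBB/RBBB) already at this scale; the timing
classes (1dAVb, AF) need the full training budget in scripts/acceptance.py.
"""

from cardiossm.ecg_io import OVERLAP_CLASSES
from cardiossm.evaluation import evaluate
from cardiossm.network import ModelConfig, build_classifier
from cardiossm.synthetic_ecg import SyntheticCohortConfig, synth_dataset
from cardiossm.trainer import TrainingConfig, train

records, _ = synth_dataset(
    SyntheticCohortConfig(n_records=400, length=2048, seed=5)
)
train_recs, test_recs = records[:320], records[320:]

model = build_classifier(
    ModelConfig(n_layers=2, model_dim=16, state_size=32), seed=0
)
print(f"model: {model.n_parameters()} parameters")
model, history = train(
    model, train_recs, TrainingConfig(epochs=25, batch_size=32, seed=0)
)
print(f"train loss {history.train_loss[0]:.3f} -> {history.train_loss[-1]:.3f}; "
      f"lr trace {history.lr[0]:.2e} -> {history.lr[-1]:.2e} (cosine)")

report = evaluate(model, test_recs, class_subset=list(OVERLAP_CLASSES))
print(report.to_frame().to_string(index=False))
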