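"""Metric suite: confusion counts, threshold metrics, AUROC/AUPRC with
brute-force oracles, weighted averaging, and the lead-masking protocol."""

import numpy as np
import pytest

from cardiossm.ecg_io import OVERLAP_CLASSES, ECGRecord, STANDARD_LEADS
from cardiossm.evaluation import (
    auprc,
    auroc,
    classification_metrics,
    confusion_counts,
    evaluate,
    mask_leads,
    robustness_curve,
    weighted_average,
)


# -- independent oracles -----------------------------------------------------

def auroc_pairwise(scores, labels):
    """Exhaustive positive-negative pair counting, ties worth 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def auprc_at_positives(scores, labels):
    """Precision at each positive's rank (descending scores), averaged."""
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    precs = [
        y[: i + 1].sum() / (i + 1) for i in range(len(y)) if y[i] == 1
    ]
    return float(np.mean(precs))


class TestConfusion:
    def test_perfect_prediction(self):
        y = np.array([[1, 0], [0, 1], [1, 1]])
        c = confusion_counts(y, y)
        assert c.fp.sum() == 0 and c.fn.sum() == 0

    def test_inverted_prediction(self):
        y = np.array([[1, 0], [0, 1]])
        c = confusion_counts(1 - y, y)
        assert c.tp.sum() == 0 and c.tn.sum() == 0

    def test_hand_enumerated_case(self):
        pred = np.array([[1], [1], [0], [0]])
        labels = np.array([[1], [0], [0], [1]])
        c = confusion_counts(pred, labels)
        assert (c.tp[0], c.fp[0], c.tn[0], c.fn[0]) == (1, 1, 1, 1)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            confusion_counts(np.array([[0.5]]), np.array([[1]]))

    def test_total_equals_record_count(self):
        rng = np.random.default_rng(0)
        pred = (rng.random((30, 4)) < 0.5).astype(int)
        labels = (rng.random((30, 4)) < 0.3).astype(int)
        c = confusion_counts(pred, labels)
        assert np.all(c.total == 30)


class TestThresholdMetrics:
    def test_accuracy_formula(self):
        c = confusion_counts(
            np.array([[1]] * 90 + [[0]] * 5 + [[1]] * 3 + [[0]] * 2),
            np.array([[1]] * 90 + [[0]] * 5 + [[0]] * 3 + [[1]] * 2),
        )
        acc, _, _, _ = classification_metrics(c)
        np.testing.assert_allclose(acc[0], 0.95)

    def test_precision_recall_f1_by_hand(self):
        # TP=2, FP=1, FN=1 -> P = R = F1 = 2/3
        pred = np.array([[1], [1], [1], [0], [0]])
        labels = np.array([[1], [1], [0], [1], [0]])
        _, prec, rec, f1 = classification_metrics(confusion_counts(pred, labels))
        np.testing.assert_allclose([prec[0], rec[0], f1[0]], [2 / 3] * 3)

    def test_degenerate_zero_convention(self):
        pred = np.array([[0], [0]])
        labels = np.array([[0], [0]])
        _, prec, rec, f1 = classification_metrics(confusion_counts(pred, labels))
        assert prec[0] == rec[0] == f1[0] == 0.0


class TestAUROC:
    def test_perfect_separation(self):
        assert auroc(np.array([0.9, 0.8, 0.3, 0.2]), np.array([1, 1, 0, 0])) == 1.0

    def test_half_concordant(self):
        # pairs: (.9,.8)+ (.9,.3)+ (.2,.8)- (.2,.3)- -> 2/4
        assert auroc(np.array([0.9, 0.2, 0.8, 0.3]), np.array([1, 1, 0, 0])) == 0.5

    def test_all_ties(self):
        assert auroc(np.full(6, 0.4), np.array([1, 0, 1, 0, 0, 1])) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auroc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_monotone_invariance_and_complement(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 40))
            s = rng.normal(size=n)
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            base = auroc(s, y)
            assert auroc(np.exp(s), y) == pytest.approx(base, abs=1e-12)
            assert auroc(3.0 * s + 7.0, y) == pytest.approx(base, abs=1e-12)
            assert auroc(-s, y) == pytest.approx(1.0 - base, abs=1e-12)

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 51))
            s = np.round(rng.random(n), 2)  # induces ties
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            assert auroc(s, y) == pytest.approx(auroc_pairwise(s, y), abs=1e-12)

    def test_matches_sklearn(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        for _ in range(20):
            s = rng.random(30)
            y = rng.integers(0, 2, 30)
            if y.sum() in (0, 30):
                continue
            assert auroc(s, y) == pytest.approx(
                sklearn_metrics.roc_auc_score(y, s), abs=1e-12
            )


class TestAUPRC:
    def test_perfect_ranking(self):
        assert auprc(np.array([0.9, 0.8, 0.1]), np.array([1, 1, 0])) == 1.0

    def test_single_positive_mid_rank(self):
        assert auprc(np.array([0.9, 0.8, 0.7]), np.array([0, 1, 0])) == 0.5

    def test_single_positive_record(self):
        assert auprc(np.array([0.42]), np.array([1])) == 1.0

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            auprc(np.array([0.1, 0.2]), np.array([0, 0]))

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 51))
            s = rng.random(n)  # continuous, tie-free a.s.
            y = rng.integers(0, 2, n)
            if y.sum() == 0:
                continue
            assert auprc(s, y) == pytest.approx(auprc_at_positives(s, y), abs=1e-12)

    def test_matches_sklearn_average_precision(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        for _ in range(20):
            s = rng.random(30)
            y = rng.integers(0, 2, 30)
            if y.sum() == 0:
                continue
            assert auprc(s, y) == pytest.approx(
                sklearn_metrics.average_precision_score(y, s), abs=1e-12
            )


class TestWeightedAverage:
    def test_equal_supports_is_mean(self):
        assert weighted_average([0.2, 0.4, 0.9], [5, 5, 5]) == pytest.approx(0.5)

    def test_hand_case(self):
        assert weighted_average([0.8, 0.4], [3, 1]) == pytest.approx(0.7)

    def test_single_class(self):
        assert weighted_average([0.63], [9]) == 0.63

    def test_zero_support_rejected(self):
        with pytest.raises(ValueError):
            weighted_average([0.5], [0])

    def test_between_min_and_max(self, rng):
        vals = rng.random(6)
        sup = rng.integers(1, 20, 6)
        w = weighted_average(vals, sup)
        assert vals.min() - 1e-12 <= w <= vals.max() + 1e-12


class _OraclePredictor:
    """Scores = labels; depends only on the stored answer key."""

    def __init__(self, y):
        self.y = np.asarray(y, dtype=float)
        self._i = 0

    def predict_proba(self, x):
        return 0.98 * self.y + 0.01


class TestEvaluate:
    def _dataset(self, rng, n=40, c=4):
        y = (rng.random((n, c)) < 0.35).astype(np.int8)
        y[0] = 1  # ensure every class has a positive
        y[1] = 0  # ... and a negative
        x = rng.standard_normal((n, 12, 64)).astype(np.float32)
        return x, y

    def test_oracle_predictor_scores_one(self, rng):
        x, y = self._dataset(rng)
        rep = evaluate(_OraclePredictor(y), (x, y),
                       class_names=OVERLAP_CLASSES)
        np.testing.assert_allclose(rep.f1, 1.0)
        np.testing.assert_allclose(rep.auroc, 1.0)
        np.testing.assert_allclose(rep.auprc, 1.0)
        np.testing.assert_allclose(rep.accuracy, 1.0)
        assert rep.weighted["f1"] == 1.0

    def test_constant_predictor_auroc_half(self, rng):
        x, y = self._dataset(rng)
        rep = evaluate(lambda a: np.full((a.shape[0], 4), 0.3), (x, y),
                       class_names=OVERLAP_CLASSES)
        np.testing.assert_allclose(rep.auroc, 0.5)

    def test_class_subset_report(self, rng):
        x, y = self._dataset(rng, c=8)
        rep = evaluate(_OraclePredictor(y), (x, y),
                       class_subset=list(OVERLAP_CLASSES))
        assert rep.class_names == OVERLAP_CLASSES
        assert len(rep.f1) == 4
        frame = rep.to_frame()
        assert list(frame["class"])[-1] == "weighted_average"
        assert len(frame) == 5

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            evaluate(lambda a: a, [])


class TestLeadMasking:
    def _record(self, rng):
        return ECGRecord(
            signal=rng.standard_normal((12, 128)), lead_names=STANDARD_LEADS
        )

    def test_k_zero_is_identity(self, rng):
        rec = self._record(rng)
        np.testing.assert_array_equal(mask_leads(rec, 0, seed=1).signal, rec.signal)

    def test_k_full_zeroes_everything(self, rng):
        rec = self._record(rng)
        assert np.all(mask_leads(rec, 12, seed=1).signal == 0)

    def test_exactly_k_rows_and_seeded(self, rng):
        rec = self._record(rng)
        m1 = mask_leads(rec, 6, seed=9)
        m2 = mask_leads(rec, 6, seed=9)
        zero_rows = np.where(~m1.signal.any(axis=1))[0]
        assert len(zero_rows) == 6
        np.testing.assert_array_equal(m1.signal, m2.signal)
        keep = np.setdiff1d(np.arange(12), zero_rows)
        np.testing.assert_array_equal(m1.signal[keep], rec.signal[keep])

    def test_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            mask_leads(self._record(rng), 13, seed=0)


class TestRobustnessCurve:
    def test_baseline_matches_evaluate_and_flat_for_blind_model(self, rng):
        n, c = 30, 4
        y = (rng.random((n, c)) < 0.4).astype(np.int8)
        y[0] = 1
        y[1] = 0
        x = rng.standard_normal((n, 12, 64)).astype(np.float32)
        oracle = _OraclePredictor(y)  # ignores the signal entirely
        res = robustness_curve(oracle, (x, y), schedule=(2, 6, 10), repeats=2,
                               seed=3, class_names=OVERLAP_CLASSES)
        assert res.ks == (0, 2, 6, 10)
        base = evaluate(oracle, (x, y), class_names=OVERLAP_CLASSES)
        assert res.f1[0] == pytest.approx(base.weighted["f1"])
        np.testing.assert_allclose(res.f1, res.f1[0])  # flat: signal unused

    def test_seeded_reproducibility(self, rng):
        n = 20
        y = (rng.random((n, 4)) < 0.4).astype(np.int8)
        y[0] = 1
        y[1] = 0
        x = rng.standard_normal((n, 12, 64)).astype(np.float32)

        def scorer(a):
            return 1.0 / (1.0 + np.exp(-a.mean(axis=2)[:, :4]))

        r1 = robustness_curve(scorer, (x, y), schedule=(4,), repeats=2, seed=7,
                              class_names=OVERLAP_CLASSES)
        r2 = robustness_curve(scorer, (x, y), schedule=(4,), repeats=2, seed=7,
                              class_names=OVERLAP_CLASSES)
        np.testing.assert_array_equal(r1.f1, r2.f1)

    def test_invalid_schedule_rejected(self, rng):
        x = rng.standard_normal((4, 12, 16)).astype(np.float32)
        y = np.ones((4, 2), dtype=np.int8)
        with pytest.raises(ValueError):
            robustness_curve(lambda a: a[:, :2, 0], (x, y), schedule=(13,))
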