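"""Metrics, threshold scanning, LOO CV, and ROC/AUC."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from protclass import SVMConfig, SyntheticSpec, generate
from protclass.evaluate import (
    ConfusionCounts,
    EvaluationError,
    confusion,
    loocv,
    metrics,
    roc_auc,
    select_best,
    threshold_grid,
    threshold_scan,
)
from protclass.sequence_io import LabeledDataset


class TestConfusion:
    def test_all_correct(self):
        c = confusion([1] * 5 + [0] * 5, [1] * 5 + [0] * 5)
        assert (c.TP, c.TN, c.FP, c.FN) == (5, 5, 0, 0)

    def test_all_flipped(self):
        c = confusion([1] * 5 + [0] * 5, [0] * 5 + [1] * 5)
        assert (c.TP, c.TN, c.FP, c.FN) == (0, 0, 5, 5)

    def test_benchmark_positive_set_counts(self):
        # 48 positives, 45 predicted positive
        t = [1] * 48
        p = [1] * 45 + [0] * 3
        c = confusion(t, p)
        assert c.TP == 45 and c.FN == 3

    def test_length_mismatch(self):
        with pytest.raises(EvaluationError):
            confusion([1, 0], [1])

    def test_non_binary(self):
        with pytest.raises(EvaluationError):
            confusion([1, 2], [1, 0])


class TestMetrics:
    def test_sensitivity_worked_example(self):
        # 49 of 56 positives recovered
        m = metrics(ConfusionCounts(TP=49, FP=27, TN=273, FN=7))
        assert m.sensitivity == pytest.approx(87.50, abs=0.01)

    def test_ppv_worked_example(self):
        # benchmark set: 47 true positives, 14 false positives
        m = metrics(ConfusionCounts(TP=47, FP=14, TN=294, FN=1))
        assert m.ppv == pytest.approx(0.77, abs=0.01)

    def test_specificity_worked_example(self):
        m = metrics(ConfusionCounts(TP=47, FP=14, TN=294, FN=1))
        assert m.specificity == pytest.approx(95.45, abs=0.01)

    def test_perfect_prediction_mcc(self):
        m = metrics(ConfusionCounts(TP=10, FP=0, TN=10, FN=0))
        assert m.mcc == 1.0

    def test_random_prediction_mcc_zero(self):
        m = metrics(ConfusionCounts(TP=5, FP=5, TN=5, FN=5))
        assert m.mcc == 0.0

    def test_degenerate_mcc_flagged(self):
        m = metrics(ConfusionCounts(TP=0, FP=0, TN=10, FN=0))
        assert m.mcc == 0.0 and m.mcc_degenerate

    def test_undefined_ppv_flagged(self):
        m = metrics(ConfusionCounts(TP=0, FP=0, TN=5, FN=5))
        assert m.ppv_undefined and m.ppv == 0.0

    # Published LOO and benchmark rows: (counts) -> expected metrics within
    # the 0.01 absolute tolerance left by display truncation.
    @pytest.mark.parametrize(
        "tp, n_pos, tn, n_neg, acc, mcc, ppv",
        [
            (49, 56, 271, 300, 89.88, 0.68, 0.62),
            (47, 56, 250, 300, 83.42, 0.55, 0.48),
            (48, 56, 259, 300, 86.23, 0.60, 0.53),
            (46, 56, 238, 300, 79.77, 0.48, 0.42),
            (49, 56, 273, 300, 90.44, 0.69, 0.64),
            (38, 48, 274, 308, None, None, 0.52),
            (45, 48, 285, 308, None, None, 0.66),
            (47, 48, 294, 308, None, None, 0.77),
            (42, 48, 277, 308, None, None, 0.57),
        ],
    )
    def test_confusion_table_arithmetic(self, tp, n_pos, tn, n_neg, acc, mcc, ppv):
        m = metrics(ConfusionCounts(TP=tp, FP=n_neg - tn, TN=tn, FN=n_pos - tp))
        assert m.sensitivity == pytest.approx(100 * tp / n_pos, abs=1e-9)
        assert m.specificity == pytest.approx(100 * tn / n_neg, abs=1e-9)
        if acc is not None:
            assert m.accuracy == pytest.approx(acc, abs=0.01)
        if mcc is not None:
            assert m.mcc == pytest.approx(mcc, abs=0.01)
        if ppv is not None:
            assert m.ppv == pytest.approx(ppv, abs=0.01)

    @pytest.mark.parametrize(
        "tp, tn, acc",
        [(38, 265, 85.11), (36, 267, 85.11), (46, 276, 90.44), (39, 269, 86.51), (38, 275, 87.92)],
    )
    def test_ann_accuracy_arithmetic(self, tp, tn, acc):
        m = metrics(ConfusionCounts(TP=tp, FP=300 - tn, TN=tn, FN=56 - tp))
        assert m.accuracy == pytest.approx(acc, abs=0.01)


class TestThresholdScan:
    def test_default_grid_has_21_points(self):
        assert len(threshold_grid()) == 21
        scores = np.linspace(-1, 1, 10)
        labels = np.array([0, 1] * 5)
        assert len(threshold_scan(scores, labels)) == 21

    def test_below_min_all_positive(self):
        scores = np.array([0.2, 0.4, -0.3, -0.5])
        labels = np.array([1, 1, 0, 0])
        rep = threshold_scan(scores, labels)[0]  # threshold -1.0
        assert rep.sensitivity == 100.0 and rep.specificity == 0.0

    def test_above_max_all_negative(self):
        scores = np.array([0.2, 0.4, -0.3, -0.5])
        labels = np.array([1, 1, 0, 0])
        rep = threshold_scan(scores, labels)[-1]  # threshold 1.0 > max
        assert rep.sensitivity == 0.0 and rep.specificity == 100.0

    def test_bad_step(self):
        with pytest.raises(EvaluationError):
            threshold_scan([0.1], [1], step=0)

    def test_counts_consistent_with_report(self):
        scores = np.array([0.35, -0.15, 0.05, -0.45, 0.55])
        labels = np.array([1, 0, 1, 0, 1])
        for rep in threshold_scan(scores, labels):
            again = metrics(rep.counts, rep.threshold)
            assert again.sensitivity == rep.sensitivity
            assert again.specificity == rep.specificity
            assert again.accuracy == rep.accuracy


class TestSelectBest:
    def _report(self, acc, sn, sp, th):
        tp = round(sn)  # build a consistent table around 100 pos / 100 neg
        tn = round(sp)
        return metrics(ConfusionCounts(TP=tp, FP=100 - tn, TN=tn, FN=100 - tp), th)

    def test_single_entry(self):
        r = self._report(80, 80, 80, 0.0)
        assert select_best([r]) is r

    def test_tie_broken_by_sn_sp_gap(self):
        a = self._report(None, 85, 75, 0.1)  # gap 10
        b = self._report(None, 81, 79, 0.2)  # gap 2, same accuracy
        assert a.accuracy == b.accuracy
        assert select_best([a, b]) is b

    def test_remaining_tie_lower_threshold(self):
        a = self._report(None, 80, 80, 0.3)
        b = self._report(None, 80, 80, -0.1)
        assert select_best([a, b]) is b

    def test_matches_exhaustive_argmax(self, small_cv):
        table = small_cv.threshold_table
        best = select_best(table)
        brute = sorted(
            table,
            key=lambda r: (-r.accuracy, abs(r.sensitivity - r.specificity), r.threshold),
        )[0]
        assert best.threshold == brute.threshold
        assert best.accuracy == max(r.accuracy for r in table)


class TestROC:
    def test_perfect_separation(self):
        curve = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert curve.auc == pytest.approx(1.0)

    def test_single_class_is_error(self):
        with pytest.raises(EvaluationError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_mann_whitney_identity(self, rng):
        """AUC equals U / (n_pos * n_neg) on a small fixture with ties."""
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.35, 0.7, 0.2, 0.5, 0.9, 0.05])
        labels = np.array([0, 0, 1, 1, 0, 1, 0, 0, 1, 0])
        u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        expected = u / (labels.sum() * (len(labels) - labels.sum()))
        assert roc_auc(scores, labels).auc == pytest.approx(expected)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.4).astype(int)
        if labels.sum() in (0, 60):
            labels[0] = 1 - labels[0]
        base = roc_auc(scores, labels).auc
        assert roc_auc(np.exp(scores), labels).auc == pytest.approx(base)
        assert roc_auc(3 * scores - 7, labels).auc == pytest.approx(base)

    def test_random_scores_auc_near_half(self, rng):
        scores = rng.random(2000)
        labels = (rng.random(2000) < 0.3).astype(int)
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_curve_monotone(self, small_cv):
        curve = small_cv.roc
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)
        assert 0.0 <= curve.auc <= 1.0


class TestLOOCV:
    def test_fold_count_identity(self):
        ds = generate(SyntheticSpec(n_pos=4, n_neg=6, length_range=(20, 30), seed=2))
        result = loocv(ds, "AAC", SVMConfig())
        assert len(result.scores) == 10
        assert set(result.per_sequence_scores) == set(ds.ids)

    def test_separable_recovery(self, small_cv):
        assert small_cv.best.accuracy >= 95.0

    def test_order_permutation_invariance(self, rng):
        """Shuffling dataset order leaves every held-out SVM score unchanged."""
        ds = generate(SyntheticSpec(n_pos=5, n_neg=7, length_range=(30, 50), seed=6))
        base = loocv(ds, "AAC", SVMConfig()).per_sequence_scores
        order = rng.permutation(len(ds))
        shuffled = LabeledDataset(
            [ds.sequences[i] for i in order], ds.labels[order]
        )
        perm = loocv(shuffled, "AAC", SVMConfig()).per_sequence_scores
        # libsvm's solver is order-sensitive only at its stopping tolerance
        for sid in base:
            assert perm[sid] == pytest.approx(base[sid], abs=1e-3)

    def test_too_small_dataset(self):
        ds = generate(SyntheticSpec(n_pos=1, n_neg=5, length_range=(20, 30), seed=1))
        with pytest.raises(EvaluationError):
            loocv(ds, "AAC", SVMConfig())

    def test_ann_loocv_runs(self):
        from protclass.classify import ANNConfig

        ds = generate(SyntheticSpec(n_pos=4, n_neg=6, length_range=(20, 40), seed=8))
        result = loocv(ds, "AAC", ANNConfig(hidden_units=2, max_cycles=30, seed=0))
        assert len(result.scores) == 10
        assert np.all((result.scores >= 0) & (result.scores <= 1))
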