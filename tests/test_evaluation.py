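"""Confusion-matrix construction and the precision/recall/F1/accuracy suite."""

import numpy as np
import pytest

from tumornet.evaluation import (ConfusionMatrix, average_reports,
                                 confusion_matrix, metrics_from_confusion,
                                 per_class_accuracy)


def brute_force_metrics(cm: np.ndarray):
    """Oracle: expand the matrix to item-level labels and count one-vs-rest."""
    true, pred = [], []
    k = cm.shape[0]
    for i in range(k):
        for j in range(k):
            true += [i] * cm[i, j]
            pred += [j] * cm[i, j]
    true, pred = np.array(true), np.array(pred)
    per = {}
    for c in range(k):
        tp = int(((true == c) & (pred == c)).sum())
        fp = int(((true != c) & (pred == c)).sum())
        fn = int(((true == c) & (pred != c)).sum())
        tn = int(((true != c) & (pred != c)).sum())
        assert tp + fp + fn + tn == len(true)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        per[c] = (p, r, f)
    acc = float((true == pred).mean())
    macro = tuple(np.mean([per[c][i] for c in range(k)]) for i in range(3))
    return per, macro, acc


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        labels = np.repeat(np.arange(4), 3)
        cm = confusion_matrix(labels, labels, 4)
        assert np.trace(cm.counts) == 12
        assert cm.counts.sum() == 12

    def test_enumeration_example(self):
        cm = confusion_matrix([0, 0, 1], [0, 1, 1], 2)
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])

    def test_row_sums_are_supports(self, rng):
        t = rng.integers(0, 4, 200)
        p = rng.integers(0, 4, 200)
        cm = confusion_matrix(t, p, 4)
        np.testing.assert_array_equal(
            cm.counts.sum(axis=1), np.bincount(t, minlength=4))

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError, match="0..3"):
            confusion_matrix([0, 4], [0, 1], 4)

    def test_csv_round_trip(self, tmp_path, rng):
        cm = confusion_matrix(rng.integers(0, 3, 30), rng.integers(0, 3, 30), 3)
        path = tmp_path / "cm.csv"
        cm.to_csv(path)
        rows = path.read_text().strip().splitlines()
        assert len(rows) == 4
        body = np.array([r.split(",")[1:] for r in rows[1:]], dtype=int)
        np.testing.assert_array_equal(body, cm.counts)


class TestMetrics:
    def test_precision_example(self):
        # TP=2, FP=1 for class 0
        cm = ConfusionMatrix(np.array([[2, 0], [1, 5]]), ["a", "b"])
        report = metrics_from_confusion(cm)
        assert report.per_class["a"]["precision"] == pytest.approx(2 / 3, abs=1e-6)

    def test_f1_harmonic_mean(self):
        # precision 1, recall 0.5 -> F1 = 2/3
        cm = ConfusionMatrix(np.array([[1, 1], [0, 5]]), ["a", "b"])
        report = metrics_from_confusion(cm)
        assert report.per_class["a"]["f1"] == pytest.approx(2 / 3, abs=1e-6)

    def test_f1_identity_per_class(self, rng):
        cm = confusion_matrix(rng.integers(0, 4, 100), rng.integers(0, 4, 100), 4)
        report = metrics_from_confusion(cm)
        for stats in report.per_class.values():
            p, r = stats["precision"], stats["recall"]
            expected = 2 * p * r / (p + r) if p + r else 0.0
            assert stats["f1"] == pytest.approx(expected, abs=1e-12)

    def test_fifty_random_matrices_match_enumeration_oracle(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 20, (4, 4))
            if counts.sum() == 0:
                counts[0, 0] = 1
            cm = ConfusionMatrix(counts, list("abcd"))
            report = metrics_from_confusion(cm)
            per, macro, acc = brute_force_metrics(counts)
            assert report.precision == pytest.approx(macro[0], abs=1e-12)
            assert report.recall == pytest.approx(macro[1], abs=1e-12)
            assert report.f1 == pytest.approx(macro[2], abs=1e-12)
            assert report.accuracy == pytest.approx(acc, abs=1e-12)
            for c, name in enumerate("abcd"):
                assert report.per_class[name]["precision"] == pytest.approx(per[c][0], abs=1e-12)
                assert report.per_class[name]["recall"] == pytest.approx(per[c][1], abs=1e-12)

    def test_against_sklearn(self, rng):
        from sklearn.metrics import precision_recall_fscore_support

        t = rng.integers(0, 4, 300)
        p = rng.integers(0, 4, 300)
        report = metrics_from_confusion(confusion_matrix(t, p, 4))
        skp, skr, skf, _ = precision_recall_fscore_support(
            t, p, average="macro", zero_division=0)
        assert report.precision == pytest.approx(skp, abs=1e-12)
        assert report.recall == pytest.approx(skr, abs=1e-12)
        assert report.f1 == pytest.approx(skf, abs=1e-12)

    def test_permutation_invariance(self, rng):
        counts = rng.integers(0, 15, (4, 4))
        perm = rng.permutation(4)
        a = metrics_from_confusion(ConfusionMatrix(counts, list("abcd")))
        b = metrics_from_confusion(
            ConfusionMatrix(counts[np.ix_(perm, perm)], [chr(97 + i) for i in perm]))
        for attr in ("precision", "recall", "f1", "accuracy"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr), abs=1e-12)

    def test_accuracy_is_trace_over_total(self, rng):
        for _ in range(100):
            counts = rng.integers(1, 10, (3, 3))
            report = metrics_from_confusion(ConfusionMatrix(counts, list("abc")))
            assert report.accuracy == pytest.approx(
                np.trace(counts) / counts.sum(), abs=1e-12)

    def test_zero_division_flagged(self):
        cm = ConfusionMatrix(np.array([[3, 0], [2, 0]]), ["a", "b"])
        report = metrics_from_confusion(cm)
        assert report.zero_division_flag
        assert report.per_class["b"]["precision"] == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(ConfusionMatrix(np.zeros((2, 2), int), ["a", "b"]))


class TestPerClassAccuracy:
    def test_diagonal_is_perfect(self):
        cm = ConfusionMatrix(np.diag([3, 4, 5]), list("abc"))
        np.testing.assert_allclose(per_class_accuracy(cm), 1.0)

    def test_arithmetic_example(self):
        cm = ConfusionMatrix(np.array([[9, 1], [2, 8]]), ["a", "b"])
        np.testing.assert_allclose(per_class_accuracy(cm), [0.9, 0.8])

    def test_mean_equals_accuracy_only_when_balanced(self):
        balanced = ConfusionMatrix(np.array([[8, 2], [3, 7]]), ["a", "b"])
        rep = metrics_from_confusion(balanced)
        assert per_class_accuracy(balanced).mean() == pytest.approx(rep.accuracy)
        skewed = ConfusionMatrix(np.array([[90, 10], [3, 7]]), ["a", "b"])
        rep2 = metrics_from_confusion(skewed)
        assert per_class_accuracy(skewed).mean() != pytest.approx(rep2.accuracy)

    def test_empty_row_flagged(self):
        cm = ConfusionMatrix(np.array([[3, 0], [0, 0]]), ["a", "b"])
        with pytest.raises(ValueError, match="b"):
            per_class_accuracy(cm)


class TestAverageReports:
    def test_arithmetic_mean(self, rng):
        reports = [
            metrics_from_confusion(
                confusion_matrix(rng.integers(0, 3, 60), rng.integers(0, 3, 60), 3))
            for _ in range(5)
        ]
        avg = average_reports(reports)
        assert avg.accuracy == pytest.approx(
            np.mean([r.accuracy for r in reports]), abs=1e-9)
        assert avg.f1 == pytest.approx(np.mean([r.f1 for r in reports]), abs=1e-9)
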