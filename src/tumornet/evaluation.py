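"""Multi-class evaluation: confusion matrices and precision/recall/F1/accuracy.

Per-class statistics use the one-vs-rest reduction of the K x K confusion
matrix (rows = true class, columns = predicted class):

    TP_c = cm[c, c]            FP_c = column sum - TP_c
    FN_c = row sum - TP_c      TN_c = total - TP_c - FP_c - FN_c

    precision = TP / (TP + FP)        recall = TP / (TP + FN)
    F1 = 2 P R / (P + R)              accuracy = trace / total

Summary precision/recall/F1 are macro (unweighted) means over classes;
support-weighted means are also computed.  Cells of the form 0/0 are defined
as 0 and flagged.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict

import numpy as np


@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["true\\pred"] + self.class_names)
            for name, row in zip(self.class_names, self.counts):
                writer.writerow([name] + [int(v) for v in row])

    def plot(self, path) -> None:
        """Render a heatmap PNG (matplotlib imported lazily)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4.5, 4))
        im = ax.imshow(self.counts, cmap="Blues")
        ax.set_xticks(range(len(self.class_names)), self.class_names, rotation=45)
        ax.set_yticks(range(len(self.class_names)), self.class_names)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        for i in range(len(self.class_names)):
            for j in range(len(self.class_names)):
                ax.text(j, i, str(self.counts[i, j]), ha="center", va="center",
                        color="black", fontsize=9)
        fig.colorbar(im)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


@dataclass
class MetricsReport:
    """Macro-averaged summary metrics (fractions in [0, 1]) plus per-class detail."""

    precision: float
    recall: float
    f1: float
    accuracy: float
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)
    weighted_precision: float = 0.0
    weighted_recall: float = 0.0
    weighted_f1: float = 0.0
    zero_division_flag: bool = False

    def as_percent(self) -> dict[str, float]:
        return {
            "precision": 100 * self.precision,
            "recall": 100 * self.recall,
            "f1": 100 * self.f1,
            "accuracy": 100 * self.accuracy,
        }

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def confusion_matrix(true_labels, predicted_labels, num_classes: int,
                     class_names: list[str] | None = None) -> ConfusionMatrix:
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("true and predicted label sequences must have equal length")
    if len(t) and (t.min() < 0 or t.max() >= num_classes
                   or p.min() < 0 or p.max() >= num_classes):
        raise ValueError(f"labels must lie in 0..{num_classes - 1}")
    counts = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    names = class_names or [f"class{i}" for i in range(num_classes)]
    return ConfusionMatrix(counts, list(names))


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("cannot compute metrics from an empty confusion matrix")
    k = counts.shape[0]
    per_class = {}
    precisions, recalls, f1s, supports = [], [], [], []
    flagged = False
    for c in range(k):
        tp = float(counts[c, c])
        fp = float(counts[:, c].sum() - tp)
        fn = float(counts[c, :].sum() - tp)
        precision, f1_p = _safe_div(tp, tp + fp)
        recall, f1_r = _safe_div(tp, tp + fn)
        f1, f1_f = _safe_div(2 * precision * recall, precision + recall)
        flagged |= f1_p or f1_r or f1_f
        support = float(counts[c, :].sum())
        per_class[cm.class_names[c]] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": support,
        }
        precisions.append(precision)
        recalls.append(recall)
        f1s.append(f1)
        supports.append(support)
    supports_arr = np.asarray(supports)
    weights = supports_arr / supports_arr.sum()
    return MetricsReport(
        precision=float(np.mean(precisions)),
        recall=float(np.mean(recalls)),
        f1=float(np.mean(f1s)),
        accuracy=float(np.trace(counts) / total),
        per_class=per_class,
        weighted_precision=float(np.dot(weights, precisions)),
        weighted_recall=float(np.dot(weights, recalls)),
        weighted_f1=float(np.dot(weights, f1s)),
        zero_division_flag=bool(flagged),
    )


def per_class_accuracy(cm: ConfusionMatrix) -> np.ndarray:
    """Diagonal over row sum — the per-class recall-style score."""
    row_sums = cm.counts.sum(axis=1)
    if (row_sums == 0).any():
        empty = [cm.class_names[i] for i in np.flatnonzero(row_sums == 0)]
        raise ValueError(f"classes with no evaluated items: {empty}")
    return cm.counts.diagonal() / row_sums


def average_reports(reports: list[MetricsReport]) -> MetricsReport:
    """Arithmetic mean of summary and per-class metrics over folds."""
    if not reports:
        raise ValueError("no reports to average")
    mean = lambda attr: float(np.mean([getattr(r, attr) for r in reports]))
    per_class: dict[str, dict[str, float]] = {}
    for name in reports[0].per_class:
        per_class[name] = {
            key: float(np.mean([r.per_class[name][key] for r in reports]))
            for key in ("precision", "recall", "f1", "support")
        }
    return MetricsReport(
        precision=mean("precision"),
        recall=mean("recall"),
        f1=mean("f1"),
        accuracy=mean("accuracy"),
        per_class=per_class,
        weighted_precision=mean("weighted_precision"),
        weighted_recall=mean("weighted_recall"),
        weighted_f1=mean("weighted_f1"),
        zero_division_flag=any(r.zero_division_flag for r in reports),
    )
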