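"""Five-fold cross-validation training harness.

Each fold trains a freshly initialized model on its training chunk with Adam,
categorical cross-entropy plus the L2 kernel penalty, dropout, and
plateau-triggered learning-rate reduction monitored on validation loss.
Every fold model is then evaluated on the single held-out test set and the
per-fold metric reports are averaged arithmetically.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict

import numpy as np

from . import autodiff as ad
from .architecture import ArchitectureSpec, ClassifierNet, build_model
from .data import LabeledImageSet
from .evaluation import (ConfusionMatrix, MetricsReport, average_reports,
                         confusion_matrix, metrics_from_confusion)
from .nn_math import LearningRateState, PlateauScheduler


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 8
    initial_lr: float = 1e-3
    lr_factor: float = 0.4
    lr_patience: int = 5
    lr_floor: float = 1e-6
    folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.folds) < 1:
            raise ValueError("epochs, batch_size and folds must be >= 1")
        if not 0 < self.lr_factor < 1:
            raise ValueError("lr_factor must lie in (0, 1)")


@dataclass
class FoldAssignment:
    fold_index: int
    train_indices: np.ndarray
    val_indices: np.ndarray


@dataclass
class CVResult:
    per_fold: list[MetricsReport]
    averaged: MetricsReport
    histories: list[list[dict]]
    fold_assignments: list[FoldAssignment]
    confusions: list[ConfusionMatrix]
    best_fold_index: int

    def to_json(self) -> str:
        payload = {
            "per_fold": [asdict(r) for r in self.per_fold],
            "averaged": asdict(self.averaged),
            "averaged_percent": self.averaged.as_percent(),
            "best_fold_index": self.best_fold_index,
            "histories": self.histories,
        }
        return json.dumps(payload, indent=2)


def make_folds(n: int, folds: int, seed: int) -> list[FoldAssignment]:
    """Shuffle 0..n-1 and partition into ``folds`` chunks (sizes within 1)."""
    if n < folds:
        raise ValueError(f"cannot split {n} items into {folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    chunks = np.array_split(perm, folds)
    assignments = []
    for k, chunk in enumerate(chunks, start=1):
        train = np.concatenate([c for i, c in enumerate(chunks) if i != k - 1])
        assignments.append(FoldAssignment(k, np.sort(train), np.sort(chunk)))
    return assignments


class Adam:
    """Adam with externally adjustable learning rate."""

    def __init__(self, params: list[ad.Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def _batch_loss(model: ClassifierNet, x: np.ndarray, onehot: np.ndarray,
                lam: float, rng: np.random.Generator):
    logits = model.forward(ad.Tensor(x), training=True, rng=rng)
    loss, probs = ad.softmax_cross_entropy(logits, onehot)
    if lam > 0:
        reg = None
        for w in model.regularized():
            sq = ad.mean(ad.mul(w, w)) * float(w.data.size)
            reg = sq if reg is None else ad.add(reg, sq)
        loss = ad.add(loss, ad.mul(reg, lam))
    return loss, probs


def evaluate_loss(model: ClassifierNet, x: np.ndarray, y: np.ndarray,
                  batch_size: int = 64) -> float:
    """Mean cross-entropy (no penalty) in inference mode."""
    total, n = 0.0, len(x)
    with ad.no_grad():
        for start in range(0, n, batch_size):
            xb = x[start:start + batch_size]
            yb = y[start:start + batch_size]
            logits = model.forward(ad.Tensor(xb))
            onehot = np.eye(model.spec.num_classes, dtype=np.float32)[yb]
            loss, _ = ad.softmax_cross_entropy(logits, onehot)
            total += float(loss.data) * len(xb)
    return total / n


def evaluate_model(model: ClassifierNet, data: LabeledImageSet) -> tuple[ConfusionMatrix, MetricsReport]:
    preds = model.predict(data.images)
    cm = confusion_matrix(data.labels, preds, model.spec.num_classes, data.class_names)
    return cm, metrics_from_confusion(cm)


def train_one_fold(model: ClassifierNet,
                   train_set: LabeledImageSet,
                   val_set: LabeledImageSet,
                   config: TrainConfig,
                   rng: np.random.Generator,
                   log=None) -> list[dict]:
    """Train ``model`` in place; return the per-epoch history."""
    if len(train_set) == 0:
        raise ValueError("empty training set")
    x, y = train_set.images, train_set.labels
    k = model.spec.num_classes
    eye = np.eye(k, dtype=np.float32)
    params = model.parameters()
    optimizer = Adam(params, lr=config.initial_lr)
    scheduler = PlateauScheduler(
        LearningRateState(config.initial_lr, config.lr_factor, config.lr_floor),
        patience=config.lr_patience,
    )
    lam = model.spec.l2_lambda
    history = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(x))
        epoch_loss, epoch_correct = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            model.zero_grad()
            loss, probs = _batch_loss(model, x[idx], eye[y[idx]], lam, rng)
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(idx)
            epoch_correct += int((probs.argmax(axis=1) == y[idx]).sum())
        val_loss = evaluate_loss(model, val_set.images, val_set.labels)
        lr_used = optimizer.lr
        optimizer.lr = scheduler.step(val_loss)
        row = {
            "epoch": epoch,
            "loss": epoch_loss / len(x),
            "accuracy": epoch_correct / len(x),
            "val_loss": val_loss,
            "lr": lr_used,
        }
        history.append(row)
        if log is not None:
            log(f"  epoch {epoch:3d}  loss {row['loss']:.4f}  "
                f"acc {row['accuracy']:.3f}  val_loss {val_loss:.4f}  lr {lr_used:.2e}")
    return history


def cross_validate(data: LabeledImageSet,
                   test: LabeledImageSet,
                   spec: ArchitectureSpec,
                   config: TrainConfig,
                   log=None,
                   keep_models: bool = False):
    """Algorithmic core of the harness: k folds over ``data``, each fold's
    freshly initialized model evaluated on the held-out ``test`` set.

    Returns a CVResult (and the fold models when ``keep_models``)."""
    assignments = make_folds(len(data), config.folds, config.seed)
    reports, histories, confusions, models = [], [], [], []
    val_losses = []
    for assignment in assignments:
        if log is not None:
            log(f"fold {assignment.fold_index}/{config.folds}")
        fold_seed = (config.seed + 1000 * assignment.fold_index) % (2 ** 31)
        rng = np.random.default_rng(fold_seed)
        model = build_model(spec, rng)
        history = train_one_fold(
            model, data.subset(assignment.train_indices),
            data.subset(assignment.val_indices), config, rng, log=log,
        )
        cm, report = evaluate_model(model, test)
        reports.append(report)
        histories.append(history)
        confusions.append(cm)
        val_losses.append(history[-1]["val_loss"])
        if keep_models:
            models.append(model)
    result = CVResult(
        per_fold=reports,
        averaged=average_reports(reports),
        histories=histories,
        fold_assignments=assignments,
        confusions=confusions,
        best_fold_index=int(np.argmin(val_losses)),
    )
    return (result, models) if keep_models else result


def write_history_csv(history: list[dict], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(history[0].keys()))
        writer.writeheader()
        writer.writerows(history)
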