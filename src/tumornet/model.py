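"""High-level modelling surface: a classifier object fitted to an image set.

``BrainTumorClassifier`` is constructed from a :class:`LabeledImageSet` (or a
class-foldered directory) plus an :class:`ArchitectureSpec`; ``fit`` runs the
80/20 split and the k-fold cross-validation protocol and returns a
``ClassificationResults`` object carrying the per-fold and averaged metrics,
training histories, confusion matrices, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .architecture import ArchitectureSpec, ClassifierNet, count_parameters
from .data import LabeledImageSet, SplitConfig, load_image_folder, train_test_split
from .evaluation import MetricsReport
from .training import CVResult, TrainConfig, cross_validate, write_history_csv


class BrainTumorClassifier:
    """Four-class MRI classifier model bound to a dataset."""

    def __init__(self, data: LabeledImageSet,
                 spec: ArchitectureSpec | None = None,
                 split: SplitConfig | None = None):
        if data.images.shape[1] == 1:
            data = data.to_three_channel()
        self.data = data
        c, h, w = data.images.shape[1:]
        self.spec = spec or ArchitectureSpec(input_shape=(c, h, w))
        if self.spec.input_shape != (c, h, w):
            raise ValueError(
                f"spec input_shape {self.spec.input_shape} does not match data {(c, h, w)}"
            )
        self.split = split or SplitConfig()

    @classmethod
    def from_folder(cls, root, target_size: tuple[int, int] = (224, 224),
                    spec: ArchitectureSpec | None = None,
                    split: SplitConfig | None = None) -> "BrainTumorClassifier":
        return cls(load_image_folder(root, target_size), spec=spec, split=split)

    def fit(self, config: TrainConfig | None = None, log=None) -> "ClassificationResults":
        config = config or TrainConfig()
        train, test = train_test_split(self.data, self.split)
        cv, models = cross_validate(train, test, self.spec, config,
                                    log=log, keep_models=True)
        return ClassificationResults(self, cv, models, train, test, config)


@dataclass
class ClassificationResults:
    """Fitted-model results: estimates, their dispersion across folds, and
    the artifacts needed to reproduce or reuse the fit."""

    model: BrainTumorClassifier
    cv: CVResult
    fold_models: list[ClassifierNet]
    train_set: LabeledImageSet
    test_set: LabeledImageSet
    config: TrainConfig

    @property
    def averaged(self) -> MetricsReport:
        return self.cv.averaged

    @property
    def best_model(self) -> ClassifierNet:
        """The fold model with the lowest final validation loss."""
        return self.fold_models[self.cv.best_fold_index]

    def predict(self, images) -> np.ndarray:
        return self.best_model.predict(np.asarray(images, dtype=np.float32))

    def summary(self) -> str:
        avg = self.cv.averaged
        lines = [
            "Brain-tumor classifier: cross-validation results",
            "=" * 58,
            f"classes: {', '.join(self.data_class_names)}",
            f"train/test sizes: {len(self.train_set)}/{len(self.test_set)}"
            f"   folds: {self.config.folds}   epochs: {self.config.epochs}",
            f"parameters: {count_parameters(self.model.spec).total:,}",
            "-" * 58,
            f"{'fold':<8}{'accuracy':>10}{'precision':>11}{'recall':>9}{'f1':>9}",
        ]
        for i, rep in enumerate(self.cv.per_fold, start=1):
            lines.append(
                f"{i:<8}{rep.accuracy:>10.4f}{rep.precision:>11.4f}"
                f"{rep.recall:>9.4f}{rep.f1:>9.4f}"
            )
        lines.append("-" * 58)
        lines.append(
            f"{'mean':<8}{avg.accuracy:>10.4f}{avg.precision:>11.4f}"
            f"{avg.recall:>9.4f}{avg.f1:>9.4f}"
        )
        pct = avg.as_percent()
        lines.append(
            f"averaged test accuracy {pct['accuracy']:.2f}%  "
            f"precision {pct['precision']:.2f}%  recall {pct['recall']:.2f}%  "
            f"F1 {pct['f1']:.2f}%"
        )
        return "\n".join(lines)

    @property
    def data_class_names(self) -> list[str]:
        return self.model.data.class_names

    def save(self, out_dir) -> Path:
        """Write the run directory: config, CV result JSON, per-fold history
        CSVs, checkpoints, and confusion-matrix CSVs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(
            self.model.spec.to_json() + "\n" +
            __import__("json").dumps(vars(self.config), indent=2)
        )
        (out / "cv_result.json").write_text(self.cv.to_json())
        for i, (hist, cm, net) in enumerate(
                zip(self.cv.histories, self.cv.confusions, self.fold_models), start=1):
            write_history_csv(hist, out / f"fold{i}_history.csv")
            cm.to_csv(out / f"fold{i}_confusion.csv")
            net.save_weights(out / f"fold{i}_weights.npz")
        (out / "summary.txt").write_text(self.summary() + "\n")
        return out
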