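"""Pure mathematical primitives of the classifier.

Activations (ReLU, sigmoid, softmax), the categorical cross-entropy loss,
the L2 weight penalty, and the plateau-triggered learning-rate update.
These are plain NumPy functions, independent of the autodiff engine, and are
the reference formulas the network layers must agree with.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: floor applied to predicted probabilities before the logarithm
CROSS_ENTROPY_EPS = 1e-7


@dataclass
class RegularizationConfig:
    """L2 (weight-decay) strength; the architecture default is 1e-3."""

    lam: float = 1e-3

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError(f"lambda must be non-negative, got {self.lam}")


@dataclass
class LearningRateState:
    """Current learning rate plus the plateau-reduction constants.

    ``factor`` multiplies the rate on a detected plateau (0.4 here);
    ``floor`` is the smallest admissible rate.
    """

    current: float = 1e-3
    factor: float = 0.4
    floor: float = 1e-6

    def __post_init__(self):
        if not 0 < self.factor < 1:
            raise ValueError(f"factor must lie in (0, 1), got {self.factor}")
        if not self.current >= self.floor > 0:
            raise ValueError(
                f"require current >= floor > 0, got current={self.current}, floor={self.floor}"
            )


def _check_finite(x: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} received a non-finite input")


def relu(x):
    """Elementwise max(0, x); shape preserved."""
    arr = np.asarray(x, dtype=float)
    _check_finite(arr, "relu")
    out = np.maximum(arr, 0.0)
    return out if arr.shape else float(out)


def sigmoid(x):
    """Logistic function 1 / (1 + e^-x), numerically stable for large |x|."""
    arr = np.asarray(x, dtype=float)
    _check_finite(arr, "sigmoid")
    out = np.empty_like(arr)
    pos = arr >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-arr[pos]))
    ez = np.exp(arr[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if arr.shape else float(out)


def softmax(z) -> np.ndarray:
    """Probability distribution e^{z_i} / sum_j e^{z_j}, max-shifted for safety."""
    arr = np.asarray(z, dtype=float)
    if arr.size == 0:
        raise ValueError("softmax requires a non-empty logit vector")
    _check_finite(arr, "softmax")
    shifted = arr - arr.max(axis=-1, keepdims=True)
    ez = np.exp(shifted)
    return ez / ez.sum(axis=-1, keepdims=True)


def categorical_cross_entropy(y_true, y_pred) -> float:
    """-sum_i y_true[i] * ln(y_pred[i]) with predictions clipped to [eps, 1]."""
    t = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: y_true {t.shape} vs y_pred {p.shape}")
    p = np.clip(p, CROSS_ENTROPY_EPS, 1.0)
    return float(-(t * np.log(p)).sum())


def l2_penalty(weights: Iterable, config: RegularizationConfig) -> float:
    """lambda times the sum of squared entries over all supplied tensors."""
    total = 0.0
    for w in weights:
        arr = np.asarray(getattr(w, "data", w), dtype=float)
        total += float((arr * arr).sum())
    return config.lam * total


def reduce_lr_on_plateau(state: LearningRateState,
                         history: Sequence[float],
                         patience: int = 5) -> LearningRateState:
    """Multiply the rate by ``factor`` when the monitored loss has plateaued.

    A plateau means none of the last ``patience`` entries strictly improves on
    the best value seen before them.  The history is ordered oldest to newest;
    with ``patience`` or fewer entries there is nothing to compare against and
    the state is returned unchanged.  The reduced rate never drops below
    ``state.floor``.
    """
    if patience < 1:
        raise ValueError(f"patience must be >= 1, got {patience}")
    history = list(history)
    if len(history) <= patience:
        return LearningRateState(state.current, state.factor, state.floor)
    recent_best = min(history[-patience:])
    earlier_best = min(history[:-patience])
    if recent_best < earlier_best:
        return LearningRateState(state.current, state.factor, state.floor)
    new_rate = max(state.current * state.factor, state.floor)
    return LearningRateState(new_rate, state.factor, state.floor)


@dataclass
class PlateauScheduler:
    """Stateful wrapper applying :func:`reduce_lr_on_plateau` once per epoch.

    After a reduction the observation window is cleared so that the next
    reduction again requires ``patience`` epochs without improvement, mirroring
    the usual callback semantics.
    """

    state: LearningRateState
    patience: int = 5
    _window: list = field(default_factory=list)

    def step(self, monitored: float) -> float:
        """Record one epoch's monitored value; return the rate to use next."""
        self._window.append(monitored)
        new_state = reduce_lr_on_plateau(self.state, self._window, self.patience)
        if new_state.current < self.state.current:
            self._window = []
        self.state = new_state
        return self.state.current

    @property
    def current(self) -> float:
        return self.state.current
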