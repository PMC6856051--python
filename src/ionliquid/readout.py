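"""Readout layers over liquid activity rates.

Two readouts are provided:

* the activity-rate readout: per-class mean firing rates select, for each
  class, the most active neurons; their weights contrast the class's rate
  against the mean rate in the other classes, and classification picks the
  readout neuron with the highest potential;
* a generic linear-regression readout (least squares to +/-1 targets,
  sign prediction) for the two-class generalization experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

__all__ = [
    "ReadoutWeights",
    "FitnessResult",
    "LinearReadout",
    "activity_rate",
    "class_mean_rates",
    "build_readout_weights",
    "classify",
    "fitness",
    "train_linear_readout",
]


def activity_rate(path) -> np.ndarray:
    """Per-neuron mean activity over a run: a_i = (1/T) sum_t x_i(t)."""
    x = np.atleast_2d(np.asarray(getattr(path, "activity", path), dtype=np.float64))
    if x.shape[0] < 1:
        raise ConfigError("need at least one time step")
    return x.mean(axis=0)


def class_mean_rates(rates, labels, classes=None) -> tuple[np.ndarray, np.ndarray]:
    """Mean rate vector per class: alpha[c, i] = mean over class-c samples of a_i.

    Returns ``(alpha, classes)`` with ``alpha`` of shape (C, N) and classes
    in sorted order (or the order given).  Every class must have >= 1 sample.
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=np.float64))
    labels = np.asarray(labels)
    if len(labels) != len(rates):
        raise ConfigError("one label per rate vector required")
    classes = np.unique(labels) if classes is None else np.asarray(classes)
    alpha = np.empty((len(classes), rates.shape[1]))
    for ci, c in enumerate(classes):
        mask = labels == c
        if not mask.any():
            raise ConfigError(f"class {c!r} has no samples")
        alpha[ci] = rates[mask].mean(axis=0)
    return alpha, classes


@dataclass(frozen=True)
class ReadoutWeights:
    """Non-negative class weights over liquid neurons.

    ``weights[c, i]`` is zero for every neuron outside the class's active
    set ``active_sets[c]`` (the ``active_set_size`` most active neurons for
    that class).
    """

    weights: np.ndarray       # (C, N) >= 0
    active_sets: np.ndarray   # (C, active_set_size) neuron indices
    classes: np.ndarray       # (C,) class labels

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def build_readout_weights(
    alpha: np.ndarray,
    active_set_size: int | None = None,
    *,
    classes=None,
    mode: str = "contrast",
) -> ReadoutWeights:
    """Connect each class's most active neurons to its readout neuron.

    ``alpha`` is the (C, N) class-mean-rate matrix.  For each class the
    ``active_set_size`` neurons with the highest class rate (ties broken by
    lowest index) form the active set; the rest get weight 0.  Within the
    active set the default ``contrast`` mode sets

        w_ic = max(0, alpha_ic - (1/(C-1)) sum_{j != c} alpha_ij),

    the class rate contrasted against the mean rate in the other classes and
    clipped at zero to keep all readout connections excitatory.  ``raw``
    mode uses w_ic = alpha_ic directly.  Default active-set size is
    ceil(0.1 * N).
    """
    alpha = np.atleast_2d(np.asarray(alpha, dtype=np.float64))
    c_n, n = alpha.shape
    if c_n < 2:
        raise ConfigError("need at least 2 classes (the contrast divides by C-1)")
    if active_set_size is None:
        active_set_size = int(np.ceil(0.1 * n))
    if not 1 <= active_set_size <= n:
        raise ConfigError(f"active_set_size must lie in [1, {n}]")
    if mode not in ("contrast", "raw"):
        raise ConfigError(f"unknown mode {mode!r}")
    if classes is None:
        classes = np.arange(c_n)

    if mode == "contrast":
        others = (alpha.sum(axis=0)[None, :] - alpha) / (c_n - 1)
        values = np.clip(alpha - others, 0.0, None)
    else:
        values = alpha.copy()

    weights = np.zeros_like(alpha)
    active = np.empty((c_n, active_set_size), dtype=np.intp)
    for c in range(c_n):
        top = np.argsort(-alpha[c], kind="stable")[:active_set_size]
        active[c] = np.sort(top)
        weights[c, top] = values[c, top]
    return ReadoutWeights(weights=weights, active_sets=active, classes=np.asarray(classes))


def classify(rates: np.ndarray, readout: ReadoutWeights):
    """Predict the class whose readout neuron has the highest potential.

    The potential of readout neuron c is the dot product of its weights with
    the sample's rate vector; ties go to the lowest class index.  Accepts a
    single rate vector or an (S, N) batch.
    """
    rates = np.asarray(rates, dtype=np.float64)
    single = rates.ndim == 1
    scores = np.atleast_2d(rates) @ readout.weights.T
    winners = readout.classes[np.argmax(scores, axis=1)]
    return winners[0] if single else winners


@dataclass(frozen=True)
class FitnessResult:
    """Classification fitness: 1 - errors / S."""

    fitness: float
    errors: int
    n_samples: int


def fitness(desired, estimated) -> FitnessResult:
    """Fraction of correctly classified samples, as a fitness in [0, 1]."""
    d = np.asarray(desired)
    e = np.asarray(estimated)
    if d.shape != e.shape:
        raise ConfigError("desired and estimated label vectors differ in length")
    errors = int(np.count_nonzero(d != e))
    return FitnessResult(fitness=1.0 - errors / len(d), errors=errors, n_samples=len(d))


@dataclass(frozen=True)
class LinearReadout:
    """Least-squares linear readout with sign decision.

    ``coef`` includes a trailing intercept; prediction is
    ``1 if [a, 1] . coef >= 0 else 0``.
    """

    coef: np.ndarray

    def decision(self, rates: np.ndarray) -> np.ndarray:
        rates = np.atleast_2d(np.asarray(rates, dtype=np.float64))
        design = np.column_stack([rates, np.ones(len(rates))])
        return design @ self.coef

    def predict(self, rates: np.ndarray) -> np.ndarray:
        """Binary class labels (0/1) by the sign of the decision value."""
        return (self.decision(rates) >= 0).astype(np.uint8)


def train_linear_readout(features, targets) -> LinearReadout:
    """Fit a minimum-norm least-squares readout to binary targets.

    ``targets`` in {0, 1} are mapped to -1/+1 internally; the fit is the
    minimum-norm solution (deterministic, well-defined for rank-deficient
    designs).
    """
    x = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if x.shape[1] < 1:
        raise ConfigError("need at least one feature column")
    y = np.asarray(targets, dtype=np.float64)
    if len(y) != len(x):
        raise ConfigError("one target per sample required")
    y = np.where(y > 0, 1.0, -1.0)
    design = np.column_stack([x, np.ones(len(x))])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return LinearReadout(coef=coef)
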