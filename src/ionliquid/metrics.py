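"""Liquid-quality metrics: pairwise separation, class separation, kernel rank.

Pairwise separation sums, over time, the L2 distance between the state
vectors evoked by two input streams.  Class ("Norton") separation compares
the inter-class center distance ``c_d`` with the mean intra-class variance
``c_v``:

    c_d   = (1/n^2) sum_{l,m} || mu(X_l) - mu(X_m) ||_2
    rho_l = mean over x in X_l of || mu(X_l) - x ||_2
    c_v   = (1/n) sum_l rho_l
    Sep   = c_d / (c_v + 1)

Note ``c_d`` averages over all ordered class pairs including l = m, whose
terms are zero — the divisor is n^2, as printed in the source formulation.
Kernel rank is the numerical rank of the neuron x stream state matrix: the
degrees of freedom a linear readout has over those streams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

__all__ = [
    "SeparationResult",
    "pairwise_separation",
    "norton_separation",
    "kernel_rank",
]


@dataclass(frozen=True)
class SeparationResult:
    """Class-separation summary: Sep = c_d / (c_v + 1)."""

    c_d: float
    c_v: float
    sep: float
    centers: dict  # class label -> center-of-mass vector

    def as_dict(self) -> dict:
        return {"c_d": self.c_d, "c_v": self.c_v, "sep": self.sep}


def pairwise_separation(path_u, path_v) -> float:
    """Sum over steps of || X_u(t) - X_v(t) ||_2 for two state paths.

    Accepts :class:`~ionliquid.dynamics.StatePath` objects or raw (T, N)
    arrays.
    """
    xu = np.asarray(getattr(path_u, "activity", path_u), dtype=np.float64)
    xv = np.asarray(getattr(path_v, "activity", path_v), dtype=np.float64)
    if xu.shape != xv.shape:
        raise ConfigError(f"state paths differ in shape: {xu.shape} vs {xv.shape}")
    return float(np.linalg.norm(xu - xv, axis=1).sum())


def state_distance_curve(path_u, path_v) -> np.ndarray:
    """Per-step L2 state distance || X_u(t) - X_v(t) ||_2 (length T)."""
    xu = np.asarray(getattr(path_u, "activity", path_u), dtype=np.float64)
    xv = np.asarray(getattr(path_v, "activity", path_v), dtype=np.float64)
    if xu.shape != xv.shape:
        raise ConfigError(f"state paths differ in shape: {xu.shape} vs {xv.shape}")
    return np.linalg.norm(xu - xv, axis=1)


def norton_separation(vectors, labels) -> SeparationResult:
    """Class separation of labeled state vectors.

    ``vectors`` is (S, N); ``labels`` assigns each row to a class.  Every
    class must be non-empty.  The result is invariant to permuting vectors
    within a class and to relabeling classes.
    """
    x = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
    labels = np.asarray(labels)
    if len(labels) != len(x):
        raise ConfigError("one label per state vector required")
    if len(x) == 0:
        raise ConfigError("need at least one state vector")
    classes = np.unique(labels)
    mus = np.stack([x[labels == c].mean(axis=0) for c in classes])
    n = len(classes)
    diff = mus[:, None, :] - mus[None, :, :]
    c_d = float(np.linalg.norm(diff, axis=2).sum() / n**2)
    rhos = [
        float(np.linalg.norm(mus[i] - x[labels == c], axis=1).mean())
        for i, c in enumerate(classes)
    ]
    c_v = float(np.mean(rhos))
    sep = c_d / (c_v + 1.0)
    centers = {c.item() if hasattr(c, "item") else c: mus[i] for i, c in enumerate(classes)}
    return SeparationResult(c_d=c_d, c_v=c_v, sep=sep, centers=centers)


def kernel_rank(m: np.ndarray, tol: float | None = None) -> int:
    """Numerical rank of the N x m matrix of per-stream state vectors.

    Column j is the state vector of input stream j at a fixed probe time
    (the final step by default elsewhere in the package).  Higher rank means
    more degrees of freedom for a linear readout.
    """
    m = np.atleast_2d(np.asarray(m, dtype=np.float64))
    if m.shape[1] < 1:
        raise ConfigError("need at least one input stream column")
    return int(np.linalg.matrix_rank(m, tol=tol))
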