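"""Neuron dynamics in the liquid: k-WTA firing with homeostatic thresholds.

Per time step, in order:

1. external events are injected into the grid,
2. the grid takes one diffusion/leak step,
3. each neuron's pre-activation is formed from the voltages under its
   dendrites, ``p_i = sum_j w_ij V(i, j) - nu_i``,
4. the ``k`` neurons with highest pre-activation fire (k-winner-take-all,
   ties broken by lowest index),
5. thresholds adapt homeostatically, ``nu_i += eta * (x_i - k/N)`` —
   intrinsic plasticity pushing every neuron's firing rate toward ``k/N``,
6. each firing neuron deposits ``spike_amplitude`` volts at its axon
   terminal, to diffuse from the next step on.

Because exactly ``k`` neurons fire each step, the threshold sum is an exact
invariant of the run.  Pre-activations are memoryless by default; an
optional leaky accumulator on ``p`` (``p_decay``) is available as an
extension and off by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .grid import DiffusionParams, VoltageGrid, _diffuse_array
from .topology import Topology

__all__ = [
    "DynamicsConfig",
    "LiquidState",
    "StatePath",
    "preactivation",
    "kwta",
    "update_thresholds",
    "axonal_feedback",
    "run_simulation",
    "pattern_to_injections",
    "liquid_rates",
]


@dataclass(frozen=True)
class DynamicsConfig:
    """Parameters of the firing dynamics.

    k : winners per step (1 <= k <= N); keep ``k/N`` small (~0.05) for a
        sparse liquid.
    eta : intrinsic plasticity rate (threshold step per firing event).
    spike_amplitude : voltage a firing axon deposits in its terminal bin.
    diffusion : grid transfer/leak coefficients.
    p_decay : optional leak on a pre-activation accumulator (0 = memoryless,
        the default dynamics).
    """

    k: int
    eta: float = 0.2
    spike_amplitude: float = 1.0
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    p_decay: float = 0.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.eta <= 0:
            raise ConfigError("eta must be > 0")
        if not (0.0 <= self.p_decay < 1.0):
            raise ConfigError("p_decay must lie in [0, 1)")


@dataclass
class LiquidState:
    """Instantaneous neuron state: binary activity, threshold, pre-activation."""

    x: np.ndarray       # (N,) uint8
    nu: np.ndarray      # (N,) float
    p: np.ndarray       # (N,) float

    @classmethod
    def initial(cls, n_neurons: int) -> "LiquidState":
        return cls(
            x=np.zeros(n_neurons, dtype=np.uint8),
            nu=np.zeros(n_neurons),
            p=np.zeros(n_neurons),
        )


@dataclass
class StatePath:
    """Time series of liquid states over a run.

    ``activity`` is the (T, N) binary matrix whose row ``t`` is the state
    vector X(t); every row sums to ``k``.  Threshold and pre-activation
    trajectories are recorded on request.
    """

    activity: np.ndarray                  # (T, N) uint8
    nu: np.ndarray | None = None          # (T, N)
    p: np.ndarray | None = None           # (T, N)

    @property
    def n_steps(self) -> int:
        return self.activity.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.activity.shape[1]

    def rates(self) -> np.ndarray:
        """Per-neuron mean firing rate over the run (the readout features)."""
        return self.activity.mean(axis=0)

    def save_csv(self, path, sidecar: dict | None = None) -> None:
        """Write the binary activity matrix as CSV (steps x neurons) plus an
        optional JSON provenance sidecar next to it."""
        p = Path(path)
        np.savetxt(p, self.activity, fmt="%d", delimiter=",")
        if sidecar is not None:
            p.with_suffix(p.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load_csv(cls, path) -> "StatePath":
        arr = np.atleast_2d(np.loadtxt(path, delimiter=",", dtype=np.uint8))
        return cls(activity=arr)


def preactivation(grid: VoltageGrid, topo: Topology, state: LiquidState) -> np.ndarray:
    """Dendritic drive minus threshold: p_i = sum_j w_ij V(i, j) - nu_i."""
    v = grid.voltage
    dx = topo.dendrite_terminals[..., 0]
    dy = topo.dendrite_terminals[..., 1]
    return (topo.dendrite_weights * v[dy, dx]).sum(axis=1) - state.nu


def kwta(p: np.ndarray, k: int) -> np.ndarray:
    """Binary winner vector: 1 for the k largest pre-activations.

    Ties are broken deterministically in favor of the lowest neuron index
    (stable sort), so equal-p prefixes win in index order.
    """
    n = len(p)
    if not 1 <= k <= n:
        raise ConfigError(f"k must lie in [1, {n}], got {k}")
    order = np.argsort(-np.asarray(p, dtype=np.float64), kind="stable")
    x = np.zeros(n, dtype=np.uint8)
    x[order[:k]] = 1
    return x


def update_thresholds(nu: np.ndarray, x: np.ndarray, eta: float, k: int, n: int) -> np.ndarray:
    """Intrinsic plasticity step: nu_i += eta * (x_i - k/N).

    Active neurons become harder to fire, inactive ones easier; with exactly
    k winners the sum of thresholds is unchanged.  Thresholds may go
    negative.
    """
    return nu + eta * (np.asarray(x, dtype=np.float64) - k / n)


def axonal_feedback(
    grid: VoltageGrid, topo: Topology, x: np.ndarray, spike_amplitude: float
) -> VoltageGrid:
    """Deposit each firing neuron's spike at its axon-terminal bin (additive)."""
    out = grid.voltage.copy()
    fired = np.asarray(x).astype(bool)
    if fired.any():
        ax = topo.axon_terminals[fired, 0]
        ay = topo.axon_terminals[fired, 1]
        np.add.at(out, (ay, ax), spike_amplitude)
    return VoltageGrid(out)


def pattern_to_injections(
    pattern,
    mapping,
    n_steps: int,
    dt_ms: float = 1.0,
    *,
    settle_steps: int = 0,
    antialias: bool = False,
) -> list[np.ndarray]:
    """Bin a multi-channel spike pattern into per-step injection events.

    Channel ``c``'s spike at time ``t`` ms becomes an event of intensity
    ``mapping.gain`` on the channel's target bin at step ``floor(t / dt)``
    (clipped to the stimulus window of ``n_steps`` steps).  With
    ``antialias=True`` the spike's charge is split linearly between the two
    adjacent steps, so sub-step timing shifts change the injection smoothly
    instead of jumping bins.  ``settle_steps`` appends input-free steps
    during which the liquid keeps evolving on its fading memory of the
    stimulus.  Returns a list of ``n_steps + settle_steps`` (m, 3) arrays.
    """
    if len(pattern.trains) > mapping.n_sources:
        raise ConfigError("pattern has more channels than the mapping has sources")
    total = n_steps + settle_steps
    steps: list[list] = [[] for _ in range(total)]
    for c, train in enumerate(pattern.trains):
        x, y = mapping.targets[c]
        for t in train.times:
            f = t / dt_ms
            s = min(int(f), n_steps - 1)
            if antialias:
                frac = f - s
                steps[s].append((x, y, mapping.gain * (1.0 - frac)))
                if frac > 0.0 and s + 1 < total:
                    steps[s + 1].append((x, y, mapping.gain * frac))
            else:
                steps[s].append((x, y, mapping.gain))
    empty = np.empty((0, 3))
    return [np.array(ev, dtype=np.float64) if ev else empty for ev in steps]


def run_simulation(
    grid0: VoltageGrid,
    topo: Topology,
    config: DynamicsConfig,
    inputs,
    *,
    initial_state: LiquidState | None = None,
    record_trajectories: bool = False,
) -> StatePath:
    """Run the full liquid for ``len(inputs)`` steps.

    ``inputs`` is a sequence of per-step event arrays ``(x, y, intensity)``
    (empty arrays for silent steps), e.g. from
    :func:`pattern_to_injections`.  The run is fully deterministic given the
    grid, topology, config and inputs.
    """
    n = topo.n_neurons
    if config.k > n:
        raise ConfigError(f"k={config.k} exceeds the {n}-neuron liquid")
    state = initial_state if initial_state is not None else LiquidState.initial(n)
    nu = state.nu.astype(np.float64).copy()
    p_acc = state.p.astype(np.float64).copy()

    v = grid0.voltage.copy()
    alpha, beta = config.diffusion.alpha, config.diffusion.beta
    dx = topo.dendrite_terminals[..., 0]
    dy = topo.dendrite_terminals[..., 1]
    ax = topo.axon_terminals[:, 0]
    ay = topo.axon_terminals[:, 1]
    w = topo.dendrite_weights
    amp = config.spike_amplitude
    k_over_n = config.k / n

    t_total = len(inputs)
    activity = np.empty((t_total, n), dtype=np.uint8)
    nu_traj = np.empty((t_total, n)) if record_trajectories else None
    p_traj = np.empty((t_total, n)) if record_trajectories else None

    for t in range(t_total):
        ev = np.asarray(inputs[t], dtype=np.float64)
        if ev.size:
            np.add.at(v, (ev[:, 1].astype(np.intp), ev[:, 0].astype(np.intp)), ev[:, 2])
        v = _diffuse_array(v, alpha, beta)
        drive = (w * v[dy, dx]).sum(axis=1) - nu
        if config.p_decay > 0.0:
            p_acc = config.p_decay * p_acc + drive
            p = p_acc
        else:
            p = drive
        x = kwta(p, config.k)
        nu += config.eta * (x - k_over_n)
        fired = x.astype(bool)
        if amp != 0.0 and fired.any():
            np.add.at(v, (ay[fired], ax[fired]), amp)
        activity[t] = x
        if record_trajectories:
            nu_traj[t] = nu
            p_traj[t] = p

    state.x = activity[-1].copy() if t_total else state.x
    state.nu = nu
    state.p = p_acc if config.p_decay > 0.0 else state.p
    return StatePath(activity=activity, nu=nu_traj, p=p_traj)


def liquid_rates(
    topo: Topology,
    patterns,
    mapping,
    config: DynamicsConfig,
    *,
    dt_ms: float = 1.0,
    n_steps: int | None = None,
    settle_steps: int = 0,
    antialias: bool = False,
) -> np.ndarray:
    """Run each spike pattern through a fresh liquid; return (S, N) rates.

    Every sample starts from a zero grid and zero thresholds so the rate
    vector depends only on the sample, the topology and the config.  Rates
    are averaged over the whole run, including any post-stimulus settling
    steps (see :func:`pattern_to_injections`).
    """
    rates = np.empty((len(patterns), topo.n_neurons))
    for s, pattern in enumerate(patterns):
        steps = n_steps if n_steps is not None else max(1, int(np.ceil(pattern.duration / dt_ms)))
        grid0 = VoltageGrid.zeros(topo.grid_width, topo.grid_height)
        inputs = pattern_to_injections(
            pattern, mapping, steps, dt_ms,
            settle_steps=settle_steps, antialias=antialias,
        )
        path = run_simulation(grid0, topo, config, inputs)
        rates[s] = path.rates()
    return rates
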