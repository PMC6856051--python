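"""Neuron/dendrite/axon placement in the liquid.

Neurons sit on a regular ``L x L`` lattice centered in the grid.  Each neuron
owns ``D`` dendrites (reading bin voltages) and one axon (writing its spike
back into a bin).  A topology is fully described by the terminal coordinates
of every dendrite and axon plus the non-negative dendrite weights — all
connections are excitatory.  Terminal coordinates are the genes the
evolutionary optimizer moves; a 25x25-neuron, 2-dendrite liquid therefore
carries (2 + 1) * 625 = 1875 genes.

Dendrite and axon lengths are drawn uniformly from configured ranges.  By
default lengths are expressed in neuron-lattice-spacing units (so a dendrite
of length 2 in a 100x100 grid with neurons every 4 bins reaches ~8 bins);
set ``length_unit='bins'`` to interpret them as raw bin distances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError, FormatError, GenerationError

__all__ = [
    "Topology",
    "TopologyConfig",
    "generate_random_topology",
    "perturb_topology",
    "chromosome_length",
    "save_topology",
    "load_topology",
]

_SCHEMA = "ionliquid-topology/1"


@dataclass(frozen=True)
class TopologyConfig:
    """Geometry of a random liquid topology.

    Lengths are uniform ranges ``(min, max)``; the defaults follow the
    liquid used throughout: 2 dendrites per neuron, dendrite reach
    0.5–2 lattice spacings, axon reach 3–5.
    """

    grid_width: int
    grid_height: int
    lattice: int                      # L: neurons form an L x L lattice
    n_dendrites: int = 2
    dendrite_length: tuple[float, float] = (0.5, 2.0)
    axon_length: tuple[float, float] = (3.0, 5.0)
    weight_mode: str = "uniform"      # "uniform" -> w = 1/D; "random" -> U[0,1]
    length_unit: str = "lattice"      # "lattice" spacings or raw "bins"

    def __post_init__(self) -> None:
        if self.lattice < 1:
            raise ConfigError("lattice must be >= 1")
        if self.n_dendrites < 1:
            raise ConfigError("n_dendrites must be >= 1")
        for name, rng_ in (("dendrite_length", self.dendrite_length),
                           ("axon_length", self.axon_length)):
            lo, hi = rng_
            if lo < 0 or hi < lo:
                raise ConfigError(f"{name} range must satisfy 0 <= min <= max")
        if self.weight_mode not in ("uniform", "random"):
            raise ConfigError(f"unknown weight_mode {self.weight_mode!r}")
        if self.length_unit not in ("lattice", "bins"):
            raise ConfigError(f"unknown length_unit {self.length_unit!r}")
        if self.lattice > min(self.grid_width, self.grid_height):
            raise ConfigError("neuron lattice does not fit in the grid")

    @property
    def spacing(self) -> int:
        """Bin distance between adjacent lattice neurons (>= 1)."""
        return max(1, min(self.grid_width, self.grid_height) // self.lattice)


@dataclass
class Topology:
    """Terminal placement of every neuron in the liquid.

    All coordinate arrays are integer bins ``(x, y)``:

    - ``neuron_positions``: (N, 2)
    - ``dendrite_terminals``: (N, D, 2)
    - ``axon_terminals``: (N, 2)
    - ``dendrite_weights``: (N, D), all >= 0
    """

    neuron_positions: np.ndarray
    dendrite_terminals: np.ndarray
    axon_terminals: np.ndarray
    dendrite_weights: np.ndarray
    grid_width: int
    grid_height: int

    def __post_init__(self) -> None:
        self.neuron_positions = np.asarray(self.neuron_positions, dtype=np.intp)
        self.dendrite_terminals = np.asarray(self.dendrite_terminals, dtype=np.intp)
        self.axon_terminals = np.asarray(self.axon_terminals, dtype=np.intp)
        self.dendrite_weights = np.asarray(self.dendrite_weights, dtype=np.float64)
        n = self.n_neurons
        if self.dendrite_terminals.shape[:1] != (n,) or self.axon_terminals.shape != (n, 2):
            raise ConfigError("terminal arrays inconsistent with neuron count")
        if self.dendrite_weights.shape != self.dendrite_terminals.shape[:2]:
            raise ConfigError("dendrite_weights shape mismatch")
        if np.any(self.dendrite_weights < 0):
            raise ConfigError("dendrite weights must be >= 0 (excitatory)")
        for arr in (self.neuron_positions,
                    self.dendrite_terminals.reshape(-1, 2),
                    self.axon_terminals):
            if np.any((arr[:, 0] < 0) | (arr[:, 0] >= self.grid_width)
                      | (arr[:, 1] < 0) | (arr[:, 1] >= self.grid_height)):
                raise ConfigError("terminal outside the grid")

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_positions)

    @property
    def n_dendrites(self) -> int:
        return self.dendrite_terminals.shape[1]

    def copy(self) -> "Topology":
        return Topology(
            neuron_positions=self.neuron_positions.copy(),
            dendrite_terminals=self.dendrite_terminals.copy(),
            axon_terminals=self.axon_terminals.copy(),
            dendrite_weights=self.dendrite_weights.copy(),
            grid_width=self.grid_width,
            grid_height=self.grid_height,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return (
            self.grid_width == other.grid_width
            and self.grid_height == other.grid_height
            and np.array_equal(self.neuron_positions, other.neuron_positions)
            and np.array_equal(self.dendrite_terminals, other.dendrite_terminals)
            and np.array_equal(self.axon_terminals, other.axon_terminals)
            and np.array_equal(self.dendrite_weights, other.dendrite_weights)
        )


def chromosome_length(topo: Topology) -> int:
    """Number of terminal-coordinate genes: (D + 1) * N."""
    return (topo.n_dendrites + 1) * topo.n_neurons


def _lattice_positions(cfg: TopologyConfig) -> np.ndarray:
    s = cfg.spacing
    span_x = s * (cfg.lattice - 1)
    span_y = s * (cfg.lattice - 1)
    off_x = (cfg.grid_width - 1 - span_x) // 2
    off_y = (cfg.grid_height - 1 - span_y) // 2
    xs = off_x + s * np.arange(cfg.lattice)
    ys = off_y + s * np.arange(cfg.lattice)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def _annulus_offsets(r_min: float, r_max: float) -> np.ndarray:
    """Integer (dx, dy) offsets with Euclidean length in [r_min, r_max]."""
    r = int(np.ceil(r_max))
    dx, dy = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1))
    dist = np.hypot(dx, dy)
    eps = 1e-9
    mask = (dist >= r_min - eps) & (dist <= r_max + eps)
    return np.column_stack([dx[mask], dy[mask]])


def generate_random_topology(cfg: TopologyConfig, seed=None) -> Topology:
    """Draw a random topology: lattice neurons, annulus-constrained terminals.

    Each terminal is a uniformly random in-grid bin whose distance from its
    neuron lies in the configured length range.  Raises
    :class:`GenerationError` naming the neuron if a range admits no in-grid
    bin.
    """
    rng = np.random.default_rng(seed)
    positions = _lattice_positions(cfg)
    n = len(positions)
    unit = cfg.spacing if cfg.length_unit == "lattice" else 1.0

    def draw(pos: np.ndarray, length: tuple[float, float], what: str, i: int) -> np.ndarray:
        offs = _annulus_offsets(length[0] * unit, length[1] * unit)
        cand = offs + pos
        ok = ((cand[:, 0] >= 0) & (cand[:, 0] < cfg.grid_width)
              & (cand[:, 1] >= 0) & (cand[:, 1] < cfg.grid_height))
        cand = cand[ok]
        if len(cand) == 0:
            raise GenerationError(
                f"no in-grid bin at {what} distance {length} from neuron {i} at {tuple(pos)}"
            )
        return cand[int(rng.integers(len(cand)))]

    dendrites = np.empty((n, cfg.n_dendrites, 2), dtype=np.intp)
    axons = np.empty((n, 2), dtype=np.intp)
    for i, pos in enumerate(positions):
        for j in range(cfg.n_dendrites):
            dendrites[i, j] = draw(pos, cfg.dendrite_length, "dendrite", i)
        axons[i] = draw(pos, cfg.axon_length, "axon", i)

    if cfg.weight_mode == "uniform":
        weights = np.full((n, cfg.n_dendrites), 1.0 / cfg.n_dendrites)
    else:
        weights = rng.uniform(0.0, 1.0, size=(n, cfg.n_dendrites))

    return Topology(
        neuron_positions=positions,
        dendrite_terminals=dendrites,
        axon_terminals=axons,
        dendrite_weights=weights,
        grid_width=cfg.grid_width,
        grid_height=cfg.grid_height,
    )


def perturb_topology(topo: Topology, move_radius: int, seed=None) -> Topology:
    """Move every dendrite/axon terminal to a random neighboring bin.

    Each terminal is displaced independently by a uniform offset in the
    ``(2r+1) x (2r+1)`` Chebyshev neighborhood and clipped to the grid.
    Neuron positions and weights are untouched.
    """
    if move_radius < 0:
        raise ConfigError("move_radius must be >= 0")
    out = topo.copy()
    if move_radius == 0:
        return out
    rng = np.random.default_rng(seed)
    r = move_radius
    for arr in (out.dendrite_terminals, out.axon_terminals):
        arr += rng.integers(-r, r + 1, size=arr.shape)
    out.dendrite_terminals[..., 0] = np.clip(out.dendrite_terminals[..., 0], 0, topo.grid_width - 1)
    out.dendrite_terminals[..., 1] = np.clip(out.dendrite_terminals[..., 1], 0, topo.grid_height - 1)
    out.axon_terminals[:, 0] = np.clip(out.axon_terminals[:, 0], 0, topo.grid_width - 1)
    out.axon_terminals[:, 1] = np.clip(out.axon_terminals[:, 1], 0, topo.grid_height - 1)
    return out


def save_topology(topo: Topology, path) -> None:
    """Write a topology as versioned, human-readable JSON."""
    doc = {
        "schema": _SCHEMA,
        "grid_width": topo.grid_width,
        "grid_height": topo.grid_height,
        "neuron_positions": topo.neuron_positions.tolist(),
        "dendrite_terminals": topo.dendrite_terminals.tolist(),
        "axon_terminals": topo.axon_terminals.tolist(),
        "dendrite_weights": topo.dendrite_weights.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def load_topology(path) -> Topology:
    """Read a topology written by :func:`save_topology`."""
    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, OSError) as exc:
        raise FormatError(f"cannot parse topology file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("schema") != _SCHEMA:
        raise FormatError(f"not a {_SCHEMA} document: {path}")
    try:
        return Topology(
            neuron_positions=np.array(doc["neuron_positions"], dtype=np.intp),
            dendrite_terminals=np.array(doc["dendrite_terminals"], dtype=np.intp),
            axon_terminals=np.array(doc["axon_terminals"], dtype=np.intp),
            dendrite_weights=np.array(doc["dendrite_weights"], dtype=np.float64),
            grid_width=int(doc["grid_width"]),
            grid_height=int(doc["grid_height"]),
        )
    except (KeyError, ValueError, ConfigError) as exc:
        raise FormatError(f"malformed topology file {path}: {exc}") from exc
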