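"""The quantized ionic liquid space (ILS): a 2D voltage grid with diffusive coupling.

The liquid is a ``height x width`` lattice of bins; bin ``(x, y)`` holds a
voltage ``V_xy`` standing in for local ionic density.  Each time step the
voltage relaxes toward its Moore (8-bin) neighborhood at transfer rate
``alpha`` and leaks globally at rate ``beta``:

    V_xy(t+1) = (1 - beta) * V_xy(t) - alpha * sum_nb (V_xy(t) - V_nb(t))

with the neighbor sum running only over in-grid bins (zero-flux boundary),
so that for ``beta = 0`` the total voltage is conserved exactly and in
general the grid sum scales by ``(1 - beta)`` per step.

Coordinates are 0-based integers with ``x`` the column and ``y`` the row;
arrays are indexed ``[y, x]``.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

from .errors import BoundsError, CapacityError, ConfigError, LiquidStateError

__all__ = [
    "VoltageGrid",
    "DiffusionParams",
    "BinMapping",
    "diffuse_step",
    "inject",
    "map_sources_to_bins",
]

#: Stability bound on the transfer coefficient: 8 neighbors, so alpha <= 1/8
#: keeps the one-step update a convex combination and prevents overshoot.
MAX_ALPHA = 0.125


@dataclass(frozen=True)
class DiffusionParams:
    """Diffusion coefficients of the liquid.

    alpha : fraction of the voltage difference transmitted to each of the
        8 neighboring bins per step (0 < alpha <= 1/8).
    beta : global leakage per step keeping the liquid from saturating
        (0 <= beta < 1).
    """

    alpha: float = 0.1
    beta: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= MAX_ALPHA):
            raise ConfigError(
                f"alpha must lie in (0, {MAX_ALPHA}] for a stable 8-neighbor "
                f"update, got {self.alpha}"
            )
        if not (0.0 <= self.beta < 1.0):
            raise ConfigError(f"beta must lie in [0, 1), got {self.beta}")


class VoltageGrid:
    """Dense voltage state of the ILS.

    The wrapped array is float64, shape ``(height, width)``, indexed
    ``[y, x]``. The shape is fixed for the lifetime of the grid.
    """

    __slots__ = ("voltage",)

    def __init__(self, voltage: np.ndarray) -> None:
        v = np.asarray(voltage, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise ConfigError(f"voltage must be a 2D array, got shape {v.shape}")
        self.voltage = v

    @classmethod
    def zeros(cls, width: int, height: int) -> "VoltageGrid":
        if width < 1 or height < 1:
            raise ConfigError("grid dimensions must be >= 1")
        return cls(np.zeros((height, width)))

    @property
    def width(self) -> int:
        return self.voltage.shape[1]

    @property
    def height(self) -> int:
        return self.voltage.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width)."""
        return self.voltage.shape

    def copy(self) -> "VoltageGrid":
        return VoltageGrid(self.voltage.copy())

    def total(self) -> float:
        return float(self.voltage.sum())

    def __repr__(self) -> str:  # pragma: no cover
        return f"VoltageGrid({self.width}x{self.height}, sum={self.total():.4g})"


@functools.lru_cache(maxsize=16)
def _neighbor_count(shape: tuple[int, int]) -> np.ndarray:
    """Number of in-grid Moore neighbors per bin (8 interior, 5 edge, 3 corner)."""
    ones = np.ones(shape)
    return _neighbor_sum(ones)


def _neighbor_sum(v: np.ndarray) -> np.ndarray:
    """Sum of the 8 in-grid neighbors of every bin (zero-flux boundary)."""
    p = np.pad(v, 1)
    return (
        p[:-2, :-2] + p[:-2, 1:-1] + p[:-2, 2:]
        + p[1:-1, :-2] + p[1:-1, 2:]
        + p[2:, :-2] + p[2:, 1:-1] + p[2:, 2:]
    )


def _diffuse_array(v: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    ncount = _neighbor_count(v.shape)
    return (1.0 - beta) * v - alpha * (ncount * v - _neighbor_sum(v))


def diffuse_step(grid: VoltageGrid, params: DiffusionParams) -> VoltageGrid:
    """Advance the liquid one diffusion/leak step (synchronous update).

    All new values are computed from time-``t`` voltages; boundary bins
    exchange only with in-grid neighbors.
    """
    v = grid.voltage
    if not np.all(np.isfinite(v)):
        raise LiquidStateError("grid contains non-finite voltages")
    return VoltageGrid(_diffuse_array(v, params.alpha, params.beta))


def inject(
    grid: VoltageGrid,
    events,
    gain: float = 1.0,
) -> VoltageGrid:
    """Add external stimulus to the liquid.

    ``events`` is a sequence of ``(x, y, intensity)`` rows (or an ``(m, 3)``
    array); each targeted bin's voltage increases by ``gain * intensity``.
    Repeated events on one bin are additive.  Returns a new grid.
    """
    ev = np.atleast_2d(np.asarray(events, dtype=np.float64))
    if ev.size == 0:
        return grid.copy()
    if ev.shape[1] != 3:
        raise ConfigError(f"events must have rows (x, y, intensity), got shape {ev.shape}")
    x = ev[:, 0].astype(np.intp)
    y = ev[:, 1].astype(np.intp)
    inten = ev[:, 2]
    if np.any(inten < 0):
        raise ConfigError("intensities must be >= 0")
    if np.any((x < 0) | (x >= grid.width) | (y < 0) | (y >= grid.height)):
        raise BoundsError("injection coordinate outside the grid")
    out = grid.voltage.copy()
    np.add.at(out, (y, x), gain * inten)
    return VoltageGrid(out)


@dataclass(frozen=True)
class BinMapping:
    """One-to-one assignment of input sources (pixels/channels) to grid bins.

    ``targets[i] = (x, y)`` is the bin receiving source ``i``; ``gain`` is the
    voltage added per unit input intensity.
    """

    targets: np.ndarray  # (n_sources, 2) int, columns (x, y)
    grid_width: int
    grid_height: int
    gain: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.targets, dtype=np.intp)
        object.__setattr__(self, "targets", t)
        if t.ndim != 2 or t.shape[1] != 2:
            raise ConfigError("targets must be an (n_sources, 2) array")
        if np.any((t[:, 0] < 0) | (t[:, 0] >= self.grid_width)
                  | (t[:, 1] < 0) | (t[:, 1] >= self.grid_height)):
            raise BoundsError("mapping target outside the grid")
        flat = t[:, 1] * self.grid_width + t[:, 0]
        if len(np.unique(flat)) != len(flat):
            raise ConfigError("mapping must be one-to-one (duplicate target bins)")

    @property
    def n_sources(self) -> int:
        return len(self.targets)

    def events(self, intensities) -> np.ndarray:
        """Turn per-source intensities into ``(x, y, intensity)`` rows.

        ``intensities`` may be a full vector (length ``n_sources``) or a
        sequence of ``(source_index, intensity)`` pairs.
        """
        arr = np.asarray(intensities, dtype=np.float64)
        if arr.ndim == 1:
            if len(arr) != self.n_sources:
                raise ConfigError("intensity vector length must equal n_sources")
            idx = np.arange(self.n_sources)
            vals = arr
        else:
            idx = arr[:, 0].astype(np.intp)
            vals = arr[:, 1]
        return np.column_stack([self.targets[idx, 0], self.targets[idx, 1], vals])


def map_sources_to_bins(
    n_sources_x: int,
    n_sources_y: int,
    grid_width: int,
    grid_height: int,
    seed=None,
    *,
    overlap_margin: int | None = None,
    gain: float = 1.0,
) -> BinMapping:
    """Randomly map an ``n_sources_x x n_sources_y`` source lattice onto the grid.

    The grid is divided into one region per source; regions are square-ish
    windows that overlap their neighbors by ``overlap_margin`` bins on each
    side (default: half a window).  Each source is assigned a uniformly
    random bin inside its region, with distinct sources landing on distinct
    bins.  Source index is row-major: ``i = sy * n_sources_x + sx``.
    """
    n_sources = n_sources_x * n_sources_y
    if n_sources > grid_width * grid_height:
        raise CapacityError(
            f"{n_sources} sources cannot map one-to-one into "
            f"{grid_width * grid_height} bins"
        )
    rng = np.random.default_rng(seed)
    side_x = -(-grid_width // n_sources_x)   # ceil
    side_y = -(-grid_height // n_sources_y)
    mx = overlap_margin if overlap_margin is not None else side_x // 2
    my = overlap_margin if overlap_margin is not None else side_y // 2

    taken: set[int] = set()
    targets = np.empty((n_sources, 2), dtype=np.intp)
    for sy in range(n_sources_y):
        for sx in range(n_sources_x):
            x0 = max(0, (sx * grid_width) // n_sources_x - mx)
            x1 = min(grid_width, (sx * grid_width) // n_sources_x + side_x + mx)
            y0 = max(0, (sy * grid_height) // n_sources_y - my)
            y1 = min(grid_height, (sy * grid_height) // n_sources_y + side_y + my)
            i = sy * n_sources_x + sx
            for _ in range(200):
                x = int(rng.integers(x0, x1))
                y = int(rng.integers(y0, y1))
                if y * grid_width + x not in taken:
                    break
            else:
                free = [
                    (x, y)
                    for y in range(y0, y1)
                    for x in range(x0, x1)
                    if y * grid_width + x not in taken
                ]
                if not free:
                    raise CapacityError(f"no free bin left in the region of source {i}")
                x, y = free[int(rng.integers(len(free)))]
            taken.add(y * grid_width + x)
            targets[i] = (x, y)
    return BinMapping(targets=targets, grid_width=grid_width,
                      grid_height=grid_height, gain=gain)
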