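"""Elitist genetic search over terminal placements.

The chromosome of an individual is the full set of dendrite/axon terminal
coordinates of its topology.  Each generation carries the best individual
over unchanged (elitism) and fills the rest of the population with
neighborhood perturbations of it — no crossover or mutation operators
beyond those local terminal moves.  Fitness is classification accuracy of
the activity-rate readout: weights are set on a stratified 70% split of the
labeled samples and the remaining 30% is classified; the split is drawn once
per GA run so fitness differences reflect topology only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dynamics import DynamicsConfig, liquid_rates
from .errors import ConfigError
from .readout import build_readout_weights, class_mean_rates, classify, fitness
from .topology import Topology, chromosome_length, perturb_topology

__all__ = [
    "Individual",
    "GAConfig",
    "spawn_generation",
    "stratified_split",
    "evaluate_individual",
    "run_ga",
]


@dataclass
class Individual:
    """A topology with its (possibly not yet evaluated) fitness."""

    topology: Topology
    fitness: float | None = None

    def copy(self) -> "Individual":
        return Individual(topology=self.topology.copy(), fitness=self.fitness)


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings: 10 individuals x 30 generations by default."""

    population: int = 10
    generations: int = 30
    move_radius: int = 1
    split: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 1:
            raise ConfigError("population must be >= 1")
        if self.generations < 1:
            raise ConfigError("generations must be >= 1")
        if not (0.0 < self.split < 1.0):
            raise ConfigError("split fraction must lie in (0, 1)")


def spawn_generation(best: Individual, cfg: GAConfig, seed=None) -> list[Individual]:
    """Next population: the elite parent unchanged plus perturbed variants."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    out = [best.copy()]
    for _ in range(cfg.population - 1):
        child = perturb_topology(best.topology, cfg.move_radius, rng)
        out.append(Individual(topology=child))
    return out


def stratified_split(labels, frac: float, seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Split sample indices per class into (train, eval) index arrays.

    Every class must end up non-empty on both sides.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, evl = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            raise ConfigError(f"class {c!r} needs >= 2 samples to split")
        idx = rng.permutation(idx)
        n_train = int(round(frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train.append(idx[:n_train])
        evl.append(idx[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(evl))


def evaluate_individual(
    ind: Individual,
    samples,
    labels,
    mapping,
    dynamics: DynamicsConfig,
    *,
    train_idx: np.ndarray,
    eval_idx: np.ndarray,
    active_set_size: int | None = None,
    dt_ms: float = 1.0,
) -> float:
    """Fitness of one topology on pre-split labeled spike patterns.

    Runs every sample through the individual's liquid, sets activity-rate
    readout weights on the training split, classifies the evaluation split
    and stores/returns the fraction correct.
    """
    labels = np.asarray(labels)
    for name, idx in (("train", train_idx), ("eval", eval_idx)):
        if len(np.unique(labels[idx])) < len(np.unique(labels)):
            raise ConfigError(f"a class is missing from the {name} split")
    rates = liquid_rates(ind.topology, samples, mapping, dynamics, dt_ms=dt_ms)
    alpha, classes = class_mean_rates(rates[train_idx], labels[train_idx])
    readout = build_readout_weights(alpha, active_set_size, classes=classes)
    predicted = classify(rates[eval_idx], readout)
    result = fitness(labels[eval_idx], predicted)
    ind.fitness = result.fitness
    return result.fitness


def run_ga(
    initial: Individual,
    samples,
    labels,
    mapping,
    dynamics: DynamicsConfig,
    cfg: GAConfig,
    *,
    active_set_size: int | None = None,
    dt_ms: float = 1.0,
) -> tuple[Individual, list[dict]]:
    """Elitist GA loop: spawn -> evaluate -> select, for cfg.generations.

    Returns the best-ever individual and a per-generation history of dicts
    ``{"generation", "best_fitness", "generation_best"}``.  With elitism the
    best-ever fitness history is non-decreasing.  The whole trajectory is a
    pure function of (initial individual, data, cfg.seed).
    """
    root = np.random.SeedSequence(cfg.seed)
    split_ss, spawn_ss = root.spawn(2)
    train_idx, eval_idx = stratified_split(labels, cfg.split, split_ss)
    spawn_rng = np.random.default_rng(spawn_ss)

    def evaluate(ind: Individual) -> float:
        if ind.fitness is None:
            evaluate_individual(
                ind, samples, labels, mapping, dynamics,
                train_idx=train_idx, eval_idx=eval_idx,
                active_set_size=active_set_size, dt_ms=dt_ms,
            )
        return ind.fitness

    best = initial.copy()
    evaluate(best)
    history: list[dict] = []
    try:
        for gen in range(cfg.generations):
            population = spawn_generation(best, cfg, spawn_rng)
            for ind in population:
                evaluate(ind)
            gen_best = max(population, key=lambda i: i.fitness)
            if gen_best.fitness >= best.fitness:
                best = gen_best.copy()
            history.append({
                "generation": gen,
                "best_fitness": best.fitness,
                "generation_best": gen_best.fitness,
            })
    except Exception as exc:
        # keep the partial trajectory reachable on abort
        exc.ga_history = history  # type: ignore[attr-defined]
        raise
    return best, history
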