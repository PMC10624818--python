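"""A deliberately classical genetic algorithm.

Minimizes a non-negative loss over fixed-length chromosomes with:

* fitness = 1/loss (a loss of exactly 0 gets a sentinel fitness of 2.0,
  strictly above any attainable reciprocal, so perfect chromosomes rank
  first);
* elitist selection — the two fittest chromosomes pass to the next
  generation unmodified, the remaining eta - 2 parents are drawn
  fitness-proportionally with replacement;
* single-point crossover at an interior point;
* one-position mutation: a single uniformly chosen gene is, with
  probability 0.5, left alone and otherwise resampled.

The algorithm is generic over a chromosome codec so the same loop
drives both the real-vector threshold search and the fixed-size
subset (seed-set) search.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Chromosome",
    "GAConfig",
    "GATrace",
    "RealVectorCodec",
    "SubsetCodec",
    "fitness_from_loss",
    "evaluate",
    "select",
    "crossover",
    "mutate",
    "run_ga",
    "performance_index",
]

ZERO_LOSS_FITNESS = 2.0  # > 1/loss for every integer loss >= 1


@dataclass
class Chromosome:
    genes: np.ndarray
    loss: float
    fitness: float


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 10
    max_generations: int = 10_000
    mutation_keep_prob: float = 0.5
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population_size must be even and >= 2")
        if self.max_generations < 0:
            raise ValueError("max_generations must be >= 0")


@dataclass
class GATrace:
    """Per-generation progress of one GA run."""

    best_loss: list[float] = field(default_factory=list)
    mean_loss: list[float] = field(default_factory=list)
    elapsed_s: list[float] = field(default_factory=list)

    @property
    def initial_loss(self) -> float:
        return self.best_loss[0]

    @property
    def final_loss(self) -> float:
        return self.best_loss[-1]

    @property
    def generations(self) -> int:
        return len(self.best_loss) - 1

    @property
    def loss_descent_rate(self) -> float:
        """(initial best loss - final best loss) / generations."""
        g = self.generations
        return 0.0 if g == 0 else (self.initial_loss - self.final_loss) / g

    @property
    def runtime_per_generation(self) -> float:
        g = self.generations
        return 0.0 if g == 0 else float(np.sum(self.elapsed_s[1:]) / g)


def fitness_from_loss(loss_value: float) -> float:
    if loss_value < 0:
        raise ValueError("loss must be non-negative")
    return ZERO_LOSS_FITNESS if loss_value == 0 else 1.0 / loss_value


def evaluate(genes: np.ndarray, objective: Callable[[np.ndarray], float]) -> Chromosome:
    loss_value = objective(genes)
    return Chromosome(genes, loss_value, fitness_from_loss(loss_value))


def select(
    population: Sequence[np.ndarray],
    fitness: np.ndarray,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Elitist + roulette-wheel parent selection.

    Slots 0-1 hold the two fittest chromosomes (ties broken by lower
    index); the remaining eta - 2 slots are drawn fitness-proportionally
    with replacement (uniformly when all fitness is zero).
    """
    fitness = np.asarray(fitness, dtype=float)
    eta = len(population)
    order = np.argsort(-fitness, kind="stable")
    parents = [population[order[0]], population[order[1]]]
    n_draws = eta - 2
    if n_draws:
        total = fitness.sum()
        p = np.full(eta, 1.0 / eta) if total <= 0 else fitness / total
        drawn = rng.choice(eta, size=n_draws, replace=True, p=p)
        parents.extend(population[i] for i in drawn)
    return parents


def crossover(
    p1: np.ndarray, p2: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Single-point crossover at an interior point c in {1..L-1}."""
    if len(p1) != len(p2):
        raise ValueError("parents must share length")
    L = len(p1)
    if L < 2:
        raise ValueError("crossover requires length >= 2")
    c = int(rng.integers(1, L))
    o1 = np.concatenate([p1[:c], p2[c:]])
    o2 = np.concatenate([p2[:c], p1[c:]])
    return o1, o2


def mutate(
    genes: np.ndarray,
    rng: np.random.Generator,
    keep_prob: float = 0.5,
) -> np.ndarray:
    """One uniformly chosen position; kept with probability keep_prob,
    otherwise resampled from Uniform[0, 1]."""
    out = genes.copy()
    pos = int(rng.integers(len(out)))
    if rng.random() >= keep_prob:
        out[pos] = rng.random()
    return out


class RealVectorCodec:
    """Chromosome = real vector in [0,1]^L, optionally with positions
    pinned to zero (inert genes that crossover/mutation cannot move)."""

    def __init__(self, length: int, zero_mask: np.ndarray | None = None):
        self.length = length
        self.zero_mask = (
            np.zeros(length, dtype=bool) if zero_mask is None else np.asarray(zero_mask, bool)
        )

    def random(self, rng: np.random.Generator) -> np.ndarray:
        genes = rng.random(self.length)
        genes[self.zero_mask] = 0.0
        return genes

    def crossover(self, p1, p2, rng):
        o1, o2 = crossover(p1, p2, rng)
        return self._clamp(o1), self._clamp(o2)

    def mutate(self, genes, rng, keep_prob=0.5):
        return self._clamp(mutate(genes, rng, keep_prob))

    def _clamp(self, genes: np.ndarray) -> np.ndarray:
        genes[self.zero_mask] = 0.0
        return genes


class SubsetCodec:
    """Chromosome = vector of N distinct item indices out of n.

    Single-point crossover on the index vectors can create duplicates;
    a repair step replaces each duplicate with a uniformly random
    non-member. Mutation swaps one member for a random non-member with
    probability 1 - keep_prob.
    """

    def __init__(self, n_items: int, subset_size: int):
        if not 1 <= subset_size <= n_items:
            raise ValueError("subset_size must lie in [1, n_items]")
        self.n_items = n_items
        self.subset_size = subset_size
        self.length = subset_size

    def random(self, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.n_items, size=self.subset_size, replace=False)

    def crossover(self, p1, p2, rng):
        if self.length < 2:
            return p1.copy(), p2.copy()
        o1, o2 = crossover(p1, p2, rng)
        return self._repair(o1, rng), self._repair(o2, rng)

    def mutate(self, genes, rng, keep_prob=0.5):
        out = genes.copy()
        if self.subset_size == self.n_items:
            return out  # the full set has no non-member to swap in
        pos = int(rng.integers(len(out)))
        if rng.random() >= keep_prob:
            out[pos] = self._draw_nonmember(out, rng)
        return out

    def _repair(self, genes: np.ndarray, rng) -> np.ndarray:
        seen: set[int] = set()
        for i, g in enumerate(genes):
            if int(g) in seen:
                genes[i] = self._draw_nonmember(genes, rng, exclude_pos=i)
            seen.add(int(genes[i]))
        return genes

    def _draw_nonmember(self, genes, rng, exclude_pos: int | None = None) -> int:
        members = {int(g) for i, g in enumerate(genes) if i != exclude_pos}
        pool = np.array([i for i in range(self.n_items) if i not in members])
        return int(pool[rng.integers(len(pool))])


def run_ga(
    objective: Callable[[np.ndarray], float],
    codec,
    cfg: GAConfig,
) -> tuple[Chromosome, GATrace]:
    """Run the GA for cfg.max_generations; fully reproducible from
    cfg.rng_seed. Returns the best chromosome ever seen and the trace."""
    rng = np.random.default_rng(cfg.rng_seed)
    eta = cfg.population_size
    trace = GATrace()

    t0 = time.perf_counter()
    population = [codec.random(rng) for _ in range(eta)]
    chroms = [evaluate(g, objective) for g in population]
    best = min(chroms, key=lambda c: c.loss)
    _record(trace, chroms, time.perf_counter() - t0)

    for _ in range(cfg.max_generations):
        t0 = time.perf_counter()
        fitness = np.array([c.fitness for c in chroms])
        parents = select([c.genes for c in chroms], fitness, rng)

        order = np.argsort(-fitness, kind="stable")
        next_chroms: list[Chromosome] = [chroms[order[0]], chroms[order[1]]]
        for i in range(2, eta, 2):
            if codec.length >= 2:
                o1, o2 = codec.crossover(parents[i].copy(), parents[i + 1].copy(), rng)
            else:
                o1, o2 = parents[i].copy(), parents[i + 1].copy()
            for o in (o1, o2):
                o = codec.mutate(o, rng, cfg.mutation_keep_prob)
                next_chroms.append(evaluate(o, objective))
        chroms = next_chroms
        gen_best = min(chroms, key=lambda c: c.loss)
        if gen_best.loss < best.loss:
            best = gen_best
        _record(trace, chroms, time.perf_counter() - t0, floor=best.loss)

    return best, trace


def _record(trace: GATrace, chroms, elapsed: float, floor: float | None = None) -> None:
    losses = [c.loss for c in chroms]
    b = min(losses) if floor is None else min(min(losses), floor)
    trace.best_loss.append(float(b))
    trace.mean_loss.append(float(np.mean(losses)))
    trace.elapsed_s.append(elapsed)


def performance_index(trace: GATrace) -> float:
    """Loss descent per generation divided by runtime per generation
    (hardware-dependent; a tuning diagnostic, not a model quantity)."""
    R = trace.runtime_per_generation
    if R <= 0:
        raise ValueError("runtime per generation must be positive")
    return trace.loss_descent_rate / R


def performance_index_from(delta_L: float, R: float) -> float:
    if R <= 0:
        raise ValueError("runtime per generation must be positive")
    return delta_L / R
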