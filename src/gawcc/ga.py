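"""Genetic algorithm over variable-length feature-index candidates.

First stage of the two-step selector.  Candidates hold feature indices
rather than fixed-length bit vectors; mutation replaces one index, crossover
swaps equal-length contiguous windows, and elitism forms each new generation
from the highest-fitness members of the parent+offspring pool.  The run
terminates once the best fitness has been constant for a configurable number
of consecutive generations, and its terminal population seeds the second
stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .candidates import CandidateSolution
from .scoring import EvaluationBudgetExceeded, SubsetEvaluator

__all__ = [
    "GaConfig",
    "auto_init_length",
    "init_population",
    "mutate",
    "crossover",
    "elitism_select",
    "ga_run",
    "GaResult",
]


@dataclass(frozen=True)
class GaConfig:
    """GA tunables; defaults follow the published configuration.

    ``init_length=None`` means the sqrt-of-n auto rule.  ``stagnation_window``
    is the number of consecutive generations the best fitness must stay
    constant (within 1e-12) before termination.
    """

    pop_size: int = 100
    mutation_rate: float = 0.30
    crossover_rate: float = 0.30
    init_length: int | None = None
    stagnation_window: int = 10
    max_generations: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        for rate in (self.mutation_rate, self.crossover_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.init_length is not None and self.init_length < 1:
            raise ValueError("init_length must be >= 1")
        if self.stagnation_window < 1:
            raise ValueError("stagnation_window must be >= 1")


@dataclass(frozen=True)
class GaResult:
    """Terminal population with cached scores and the best-score trajectory."""

    population: tuple[CandidateSolution, ...]
    scores: tuple[float, ...]
    trajectory: tuple[float, ...]
    generations: int

    @property
    def best(self) -> CandidateSolution:
        return self.population[int(np.argmax(self.scores))]

    @property
    def best_score(self) -> float:
        return max(self.scores)


def auto_init_length(n: int) -> int:
    """Initial candidate length: min(n, max(2, round(sqrt(n))))."""
    return min(n, max(2, round(math.sqrt(n))))


def _draw_index(rng, n: int) -> int:
    """Uniform feature index in [1, n]."""
    return int(rng.integers(1, n + 1))


def init_population(n: int, cfg: GaConfig, rng) -> list[CandidateSolution]:
    """Random initial population.

    Each candidate draws ``init_length`` indices uniformly from [1, n] with
    replacement; repeated draws collapse, so initial lengths may already
    differ.
    """
    if n < 1:
        raise ValueError("need at least one feature")
    length = cfg.init_length if cfg.init_length is not None else auto_init_length(n)
    if length < 1:
        raise ValueError("init_length must be >= 1")
    pop = []
    for _ in range(cfg.pop_size):
        draws = [_draw_index(rng, n) for _ in range(length)]
        pop.append(CandidateSolution.from_values(draws))
    return pop


def mutate(cs: CandidateSolution, n: int, rng) -> CandidateSolution:
    """Replace one randomly chosen position's value with a uniform draw from [1, n].

    The result is deduplicated and sorted, so a collision shrinks the
    candidate by one.  The input is never modified.
    """
    values = list(cs.indices)
    pos = int(rng.integers(0, len(values)))
    values[pos] = _draw_index(rng, n)
    return CandidateSolution.from_values(values)


def crossover(
    a: CandidateSolution, b: CandidateSolution, rng
) -> tuple[CandidateSolution, CandidateSolution]:
    """Swap equal-length contiguous windows between two parents.

    The window length L is uniform in [1, min(len(a), len(b))] and the
    window start is shared (so crossing a candidate with itself is a
    fixed point).  Children are deduplicated and sorted and may be shorter
    than their parents.
    """
    va, vb = list(a.indices), list(b.indices)
    L = int(rng.integers(1, min(len(va), len(vb)) + 1))
    sa = sb = int(rng.integers(0, min(len(va), len(vb)) - L + 1))
    ca = va[:sa] + vb[sb : sb + L] + va[sa + L :]
    cb = vb[:sb] + va[sa : sa + L] + vb[sb + L :]
    return CandidateSolution.from_values(ca), CandidateSolution.from_values(cb)


def _rank_key(score: float, cs: CandidateSolution):
    # higher fitness first; ties -> shorter candidate, then lexicographic indices
    return (-score, len(cs), cs.indices)


def elitism_select(
    pool: list[CandidateSolution], scores: list[float], out_size: int
) -> tuple[list[CandidateSolution], list[float]]:
    """Keep the ``out_size`` highest-fitness members, deterministically."""
    if len(pool) != len(scores):
        raise ValueError("scores must align with pool")
    if out_size > len(pool):
        raise ValueError("out_size exceeds pool size")
    order = sorted(range(len(pool)), key=lambda i: _rank_key(scores[i], pool[i]))
    keep = order[:out_size]
    return [pool[i] for i in keep], [scores[i] for i in keep]


def ga_run(
    evaluator: SubsetEvaluator,
    cfg: GaConfig,
    rng=None,
) -> GaResult:
    """Run the GA to stagnation (or the generation cap).

    Per generation: ``crossover_rate * pop_size / 2`` random pairs produce
    children and ``mutation_rate * pop_size`` random members produce mutants;
    parents, children and mutants compete in one elitism pool that is cut
    back to ``pop_size``.
    """
    n = evaluator.n_features
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pop = init_population(n, cfg, rng)
    scores: list[float] = []
    try:
        for cs in pop:
            scores.append(evaluator.fitness(cs))
    except EvaluationBudgetExceeded:
        pop = pop[: len(scores)]
        if not pop:
            raise
        return GaResult(tuple(pop), tuple(scores), (max(scores),), 0)

    trajectory: list[float] = []
    best_prev = -np.inf
    streak = 0
    generations = 0
    exhausted = False
    n_pairs = round(cfg.crossover_rate * cfg.pop_size / 2)
    n_mut = round(cfg.mutation_rate * cfg.pop_size)

    for generations in range(1, cfg.max_generations + 1):
        best = max(scores)
        trajectory.append(best)
        if exhausted:
            break
        if abs(best - best_prev) <= 1e-12:
            streak += 1
            if streak >= cfg.stagnation_window:
                break
        else:
            streak = 0
        best_prev = best

        pool = list(pop)
        pool_scores = list(scores)
        try:
            for _ in range(n_pairs):
                i, j = rng.integers(0, cfg.pop_size, size=2)
                for child in crossover(pop[int(i)], pop[int(j)], rng):
                    score = evaluator.fitness(child)
                    pool.append(child)
                    pool_scores.append(score)
            for _ in range(n_mut):
                i = int(rng.integers(0, cfg.pop_size))
                m = mutate(pop[i], n, rng)
                score = evaluator.fitness(m)
                pool.append(m)
                pool_scores.append(score)
        except EvaluationBudgetExceeded:
            exhausted = True  # keep what was scored; one final selection
        pop, scores = elitism_select(pool, pool_scores, cfg.pop_size)

    return GaResult(
        population=tuple(pop),
        scores=tuple(scores),
        trajectory=tuple(trajectory),
        generations=generations,
    )
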