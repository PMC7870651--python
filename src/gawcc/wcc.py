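"""World-competitive-contests stage: attacking, transferring and passing
operators with greedy accept-if-improved search.

The optimizer receives a scored population (from the GA in the two-step
method, or randomly initialized when run standalone) and, for a fixed number
of iterations, gives every member ``match_time`` attempts to change.  Each
attempt applies the three operators in sequence — attacking (several random
positions re-drawn from the full feature range), transferring (values
imported from the current top-scoring candidates) and passing (a single
position re-drawn) — and a change is kept only if it strictly increases the
fitness.  Candidate repair (dedup + sort) may shrink a candidate, which is
how the method trims the selected-feature count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .candidates import CandidateSolution
from .ga import GaConfig, _draw_index, elitism_select, init_population
from .scoring import EvaluationBudgetExceeded, SubsetEvaluator

__all__ = [
    "WccConfig",
    "attacking",
    "transferring",
    "passing",
    "greedy_step",
    "wcc_run",
    "WccResult",
    "random_seed_population",
]


@dataclass(frozen=True)
class WccConfig:
    """WCC tunables; defaults follow the published standalone configuration.

    ``match_time`` is the number of attempts to change each candidate per
    iteration (2 standalone, 1 inside the two-step method); ``top_count`` is
    the number of highest-score candidates feeding the transferring operator.
    """

    pop_size: int = 20
    match_time: int = 2
    iterations: int = 100
    top_count: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 1 or self.iterations < 0 or self.match_time < 0:
            raise ValueError("pop_size, iterations, match_time must be non-negative")
        if not 1 <= self.top_count <= self.pop_size:
            raise ValueError("top_count must lie in [1, pop_size]")


@dataclass(frozen=True)
class WccResult:
    """Final population, cached scores and the per-iteration best trajectory."""

    population: tuple[CandidateSolution, ...]
    scores: tuple[float, ...]
    trajectory: tuple[float, ...]

    @property
    def best(self) -> CandidateSolution:
        return self.population[int(np.argmax(self.scores))]

    @property
    def best_score(self) -> float:
        return max(self.scores)


def attacking(cs: CandidateSolution, n: int, rng) -> CandidateSolution:
    """Re-draw k random positions (k uniform in [1, len(cs)]) from [1, n]."""
    values = list(cs.indices)
    k = int(rng.integers(1, len(values) + 1))
    for _ in range(k):
        pos = int(rng.integers(0, len(values)))
        values[pos] = _draw_index(rng, n)
    return CandidateSolution.from_values(values)


def transferring(
    cs: CandidateSolution, top: list[CandidateSolution], rng
) -> CandidateSolution:
    """Import values from the top-scoring candidates.

    R (uniform in [1, len(top)]) times: pick a donor uniformly, then
    overwrite k (uniform in [1, len(cs)]) random positions with uniformly
    chosen donor values.  Every output value therefore comes from the input
    or a donor.
    """
    if not top:
        raise ValueError("transferring needs a non-empty top list")
    values = list(cs.indices)
    R = int(rng.integers(1, len(top) + 1))
    for _ in range(R):
        donor = top[int(rng.integers(0, len(top)))]
        k = int(rng.integers(1, len(values) + 1))
        for _ in range(k):
            pos = int(rng.integers(0, len(values)))
            values[pos] = donor.indices[int(rng.integers(0, len(donor)))]
    return CandidateSolution.from_values(values)


def passing(cs: CandidateSolution, n: int, rng) -> CandidateSolution:
    """Overwrite exactly one random position with a uniform draw from [1, n]."""
    values = list(cs.indices)
    pos = int(rng.integers(0, len(values)))
    values[pos] = _draw_index(rng, n)
    return CandidateSolution.from_values(values)


def greedy_step(
    cs: CandidateSolution,
    proposal: CandidateSolution,
    evaluator: SubsetEvaluator,
) -> CandidateSolution:
    """Accept the proposal iff it strictly increases the fitness; ties keep
    the incumbent."""
    return proposal if evaluator.fitness(proposal) > evaluator.fitness(cs) else cs


def _top_list(
    pop: list[CandidateSolution], scores: list[float], count: int
) -> list[CandidateSolution]:
    top, _ = elitism_select(pop, scores, min(count, len(pop)))
    return top


def wcc_run(
    evaluator: SubsetEvaluator,
    seed_pop: list[CandidateSolution],
    cfg: WccConfig,
    rng=None,
) -> WccResult:
    """Run the WCC stage on a seed population.

    If the seed population exceeds ``cfg.pop_size`` it is elitism-truncated
    (the two-step method passes the GA's full population and a matching
    ``pop_size``).  Each iteration refreshes the transferring top list, then
    gives every member ``match_time`` attempts; an attempt applies
    attacking, transferring and passing in sequence with a greedy
    accept-if-improved step after each operator.
    """
    if not seed_pop:
        raise ValueError("seed population must be non-empty")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = evaluator.n_features
    pop = list(seed_pop)
    scores = [evaluator.fitness(cs) for cs in pop]
    if len(pop) > cfg.pop_size:
        pop, scores = elitism_select(pop, scores, cfg.pop_size)

    trajectory: list[float] = []
    exhausted = False
    for _ in range(cfg.iterations):
        top = _top_list(pop, scores, cfg.top_count)
        for i, member in enumerate(pop):
            try:
                for _ in range(cfg.match_time):
                    for op in ("attacking", "transferring", "passing"):
                        if op == "attacking":
                            proposal = attacking(member, n, rng)
                        elif op == "transferring":
                            proposal = transferring(member, top, rng)
                        else:
                            proposal = passing(member, n, rng)
                        member = greedy_step(member, proposal, evaluator)
            except EvaluationBudgetExceeded:
                exhausted = True  # incumbent is always scored; keep it
            pop[i] = member
            scores[i] = evaluator.fitness(member)
            if exhausted:
                break
        trajectory.append(max(scores))
        if exhausted:
            break

    return WccResult(
        population=tuple(pop), scores=tuple(scores), trajectory=tuple(trajectory)
    )


def random_seed_population(
    evaluator: SubsetEvaluator, cfg: WccConfig, rng=None
) -> list[CandidateSolution]:
    """Standalone-WCC initialization: random candidates via the GA init rule."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ga_cfg = GaConfig(pop_size=cfg.pop_size, seed=cfg.seed)
    return init_population(evaluator.n_features, ga_cfg, rng)
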