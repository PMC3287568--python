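"""Self-adaptive evolutionary programming for kernel/hyperparameter search.

Each candidate carries object parameters gamma (e.g. log10 sigma, degree,
latent-variable count) together with positive strategy parameters v that
set its own mutation scale.  Mutation first perturbs the strategy vector
log-normally,

    v_i' = v_i * exp( N(0,1) / sqrt(2 m)  +  N_i(0,1) / sqrt(2 sqrt(m)) ),

with one normal draw shared across the m parameters and one per parameter,
then moves each object parameter by a Cauchy step scaled by the new
strategy value,

    gamma_i' = gamma_i + C_i * v_i',

whose heavy tails allow occasional long jumps out of local basins.
Survival is by q-opponent tournament: each of the 2N candidates (parents
plus mutants) scores a win for every one of q random opponents whose
fitness it matches or beats, and the top half by win count (fitness as
tie-break) forms the next generation.

The kernel family is treated as a categorical gene mutated to a uniformly
random choice with small probability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Probability that mutation reassigns the categorical kernel-family gene.
FAMILY_MUTATION_PROB = 0.1


@dataclass(frozen=True)
class GeneSpec:
    """Bounds for one object parameter; integers are rounded after mutation."""

    name: str
    low: float
    high: float
    integer: bool = False

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValidationError(f"gene {self.name}: need low < high")


@dataclass(frozen=True)
class ParameterSpace:
    genes: tuple[GeneSpec, ...]
    families: tuple[str, ...] | None = None
    family_mutation_prob: float = FAMILY_MUTATION_PROB

    @property
    def m(self) -> int:
        return len(self.genes)


@dataclass
class EPCandidate:
    gamma: np.ndarray
    v: np.ndarray
    family: str | None = None
    fitness: float = -math.inf
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.gamma.shape != self.v.shape:
            raise ValidationError("gamma and v must have the same length")
        if np.any(self.v <= 0):
            raise ValidationError("strategy parameters must be positive")


def _clip_round(gamma: np.ndarray, space: ParameterSpace) -> np.ndarray:
    lo = np.array([g.low for g in space.genes])
    hi = np.array([g.high for g in space.genes])
    gamma = np.clip(gamma, lo, hi)
    ints = np.array([g.integer for g in space.genes])
    gamma[ints] = np.round(gamma[ints])
    return gamma


def candidate_params(cand: EPCandidate, space: ParameterSpace) -> dict:
    """Named view of a candidate's object parameters."""
    out = {g.name: (int(v) if g.integer else float(v))
           for g, v in zip(space.genes, cand.gamma)}
    if cand.family is not None:
        out["family"] = cand.family
    return out


def mutate(parent: EPCandidate, space: ParameterSpace, rng) -> EPCandidate:
    """Self-adaptive log-normal strategy update plus Cauchy object step."""
    m = space.m
    shared = rng.standard_normal()
    per_gene = rng.standard_normal(m)
    v_new = parent.v * np.exp(
        shared / math.sqrt(2.0 * m) + per_gene / math.sqrt(2.0 * math.sqrt(m))
    )
    cauchy = rng.standard_cauchy(m)
    gamma_new = _clip_round(parent.gamma + cauchy * v_new, space)
    family = parent.family
    if space.families and rng.random() < space.family_mutation_prob:
        family = str(rng.choice(space.families))
    return EPCandidate(gamma=gamma_new, v=v_new, family=family)


def tournament_select(
    pool: list[EPCandidate], q: int, rng
) -> list[EPCandidate]:
    """Keep the top half of the pool by wins against q random opponents."""
    n = len(pool)
    if n < 2 or n % 2:
        raise ValidationError("pool size must be even and >= 2")
    if not 1 <= q < n:
        raise ValidationError(f"q={q} must satisfy 1 <= q < pool size {n}")
    fitness = np.array([c.fitness for c in pool])
    wins = np.empty(n, dtype=int)
    for i in range(n):
        others = np.delete(np.arange(n), i)
        opponents = rng.choice(others, size=q, replace=False)
        wins[i] = int(np.sum(fitness[i] >= fitness[opponents]))
    # Sort by wins, then fitness; stable so earlier pool order breaks ties.
    order = np.lexsort((-fitness, -wins))
    return [pool[i] for i in order[: n // 2]]


def _initial_population(
    space: ParameterSpace, pop_size: int, rng
) -> list[EPCandidate]:
    lo = np.array([g.low for g in space.genes])
    hi = np.array([g.high for g in space.genes])
    pop = []
    for _ in range(pop_size):
        gamma = _clip_round(rng.uniform(lo, hi), space)
        v = (hi - lo) / 10.0  # initial step scale: a tenth of each range
        family = str(rng.choice(space.families)) if space.families else None
        pop.append(EPCandidate(gamma=gamma, v=v.copy(), family=family))
    return pop


def _evaluate(candidates, objective, space) -> None:
    for cand in candidates:
        if np.isfinite(cand.fitness):
            continue
        try:
            cand.fitness = float(objective(cand))
        except Exception as exc:  # a failed candidate loses every tournament
            logger.warning("objective failed for %s: %s",
                           candidate_params(cand, space), exc)
            cand.fitness = -math.inf


def ep_optimize(
    objective,
    space: ParameterSpace,
    pop_size: int = 20,
    generations: int = 50,
    q: int = 10,
    seed: int = 0,
    mutate_fn=mutate,
) -> tuple[EPCandidate, pd.DataFrame]:
    """Evolve ``pop_size`` candidates for ``generations`` rounds.

    ``objective`` maps an :class:`EPCandidate` to a fitness to maximize;
    a candidate on which it raises is assigned -inf fitness.  Returns the
    best candidate ever evaluated and a per-generation history of best and
    mean population fitness.
    """
    if pop_size < 2 or pop_size % 2:
        raise ValidationError("pop_size must be even and >= 2")
    if generations < 1:
        raise ValidationError("generations must be >= 1")
    rng = np.random.default_rng(seed)
    population = _initial_population(space, pop_size, rng)
    _evaluate(population, objective, space)
    best = max(population, key=lambda c: c.fitness)
    history = []
    for gen in range(generations):
        children = [mutate_fn(parent, space, rng) for parent in population]
        _evaluate(children, objective, space)
        pool = population + children
        gen_best = max(pool, key=lambda c: c.fitness)
        if gen_best.fitness > best.fitness:
            best = gen_best
        population = tournament_select(pool, q, rng)
        fits = [c.fitness for c in population if np.isfinite(c.fitness)]
        history.append({
            "generation": gen + 1,
            "best_fitness": best.fitness,
            "mean_fitness": float(np.mean(fits)) if fits else -math.inf,
        })
    best = replace(best)
    best.params = candidate_params(best, space)
    return best, pd.DataFrame(history)
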