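"""Genetic algorithm over mixed continuous/categorical parameter spaces.

The optimizer maximizes a (possibly ``-inf``-valued) objective.  Each
generation is composed of elites, mutants, crossover offspring and fresh
random candidates in fixed proportions; the two mutation hyperparameters
adapt generation-wise by the one-fifth success rule.  The search stops after
a fixed number of generations without improvement of the best fitness, or
when an evaluation budget is exhausted.  Repeated candidate vectors are
served from a cache and are not recounted as evaluations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .demography import ParameterSpace

__all__ = [
    "GAConfig", "Candidate", "OptimizeResult",
    "initial_design", "mutate", "crossover", "next_generation",
    "adapt", "optimize", "composition_counts",
]

_GEN_SIZES = (10, 50, 100)
_N_INIT_CONSTS = (5, 10, 20)


@dataclass(frozen=True)
class GAConfig:
    """The ten hyperparameters of the genetic algorithm.

    Two presets are packaged: :meth:`default` (the original configuration)
    and :meth:`new_default` (the configuration found by hyperparameter
    optimization, attempt 2).
    """

    gen_size: int = 10
    n_init_const: int = 10
    p_elitism: float = 0.20
    p_mutation: float = 0.30
    p_crossover: float = 0.30
    p_random: float = 0.20
    mutation_strength: float = 0.200
    const_mutation_strength: float = 1.010
    mutation_rate: float = 0.200
    const_mutation_rate: float = 1.020
    max_no_improvement: int | None = None
    eval_budget: int | None = None

    def __post_init__(self):
        if self.gen_size not in _GEN_SIZES:
            raise ValueError(f"gen_size must be one of {_GEN_SIZES}")
        if self.n_init_const not in _N_INIT_CONSTS:
            raise ValueError(f"n_init_const must be one of {_N_INIT_CONSTS}")
        fracs = (self.p_elitism, self.p_mutation, self.p_crossover, self.p_random)
        if any(not 0.0 <= p <= 1.0 for p in fracs):
            raise ValueError("composition fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("composition fractions must sum to 1")
        for name in ("mutation_strength", "mutation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("const_mutation_strength", "const_mutation_rate"):
            if not 1.0 <= getattr(self, name) <= 2.0:
                raise ValueError(f"{name} must lie in [1, 2]")

    @property
    def fractions(self):
        return (self.p_elitism, self.p_mutation, self.p_crossover, self.p_random)

    @property
    def stop_iterations(self) -> int:
        """Generations without improvement before stopping (1000 / gen_size)."""
        if self.max_no_improvement is not None:
            return self.max_no_improvement
        return 1000 // self.gen_size

    @classmethod
    def default(cls, **kw) -> "GAConfig":
        return cls(**kw)

    @classmethod
    def new_default(cls, **kw) -> "GAConfig":
        base = dict(gen_size=10, n_init_const=10,
                    p_elitism=0.30, p_mutation=0.20, p_crossover=0.30,
                    p_random=0.20, mutation_strength=0.776,
                    const_mutation_strength=1.302, mutation_rate=0.273,
                    const_mutation_rate=1.475)
        base.update(kw)
        return cls(**base)


@dataclass
class Candidate:
    values: tuple
    fitness: float | None = None
    provenance: str = "initial"

    def __post_init__(self):
        self.values = tuple(self.values)

    @property
    def evaluated(self) -> bool:
        return self.fitness is not None


@dataclass
class OptimizeResult:
    best: Candidate
    trace: list
    evaluations: int
    seed: int | None
    termination: str
    population: list = field(default_factory=list)
    mutation_strength: float = 0.0
    mutation_rate: float = 0.0


class CachingObjective:
    """Counts true objective calls; identical vectors hit a cache."""

    def __init__(self, objective):
        self._objective = objective
        self.cache = {}
        self.calls = 0

    def __call__(self, values):
        key = tuple(values)
        if key in self.cache:
            return self.cache[key]
        self.calls += 1
        fitness = float(self._objective(list(values)))
        if math.isnan(fitness):
            fitness = float("-inf")
        self.cache[key] = fitness
        return fitness


def _sorted_population(population):
    """Sort by fitness descending; stable, so earlier candidates win ties."""
    return sorted(population, key=lambda c: -c.fitness)


def _mutable_indices(space: ParameterSpace):
    out = []
    for k, v in enumerate(space):
        if v.fixed:
            continue
        if v.kind == "categorical" and len(v.categories) < 2:
            continue
        out.append(k)
    return out


def composition_counts(fractions, gen_size: int):
    """Largest-remainder apportionment of gen_size among the fractions."""
    quotas = [f * gen_size for f in fractions]
    counts = [int(math.floor(q)) for q in quotas]
    remainder = gen_size - sum(counts)
    order = sorted(range(len(fractions)),
                   key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return tuple(counts)


def initial_design(space: ParameterSpace, config: GAConfig, rng, objective):
    """Sample and evaluate gen_size * n_init_const candidates, keep the best gen_size."""
    if space.dimension == 0:
        raise ValueError("parameter space has no free variables")
    candidates = []
    for _ in range(config.gen_size * config.n_init_const):
        c = Candidate(space.sample(rng), provenance="initial")
        c.fitness = objective(c.values)
        candidates.append(c)
    population = _sorted_population(candidates)[:config.gen_size]
    if all(c.fitness == float("-inf") for c in population):
        raise RuntimeError(
            "every initial candidate evaluated to -inf; review parameter bounds")
    return population


def mutate(candidate: Candidate, space: ParameterSpace, strength: float,
           rate: float, rng) -> Candidate:
    """Mutate each free variable with probability ``strength``.

    Continuous values are perturbed multiplicatively, ``x (1 +/- delta)``
    with half-normal ``delta`` of scale ``rate``, then clipped to bounds;
    categorical values are resampled uniformly among the other categories.
    At least one variable always mutates.
    """
    mutable = _mutable_indices(space)
    if not mutable:
        raise ValueError("no mutable variables in the space")
    while True:
        mask = rng.random(len(mutable)) < strength
        if mask.any():
            break
    values = list(candidate.values)
    for flag, k in zip(mask, mutable):
        if not flag:
            continue
        var = space.variables[k]
        if var.kind == "categorical":
            others = [c for c in var.categories if c != values[k]]
            values[k] = others[rng.integers(len(others))]
        else:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            delta = abs(rng.normal(0.0, rate))
            values[k] = var.clip(values[k] * (1.0 + sign * delta))
    return Candidate(values, provenance="mutant")


def crossover(parent1: Candidate, parent2: Candidate, rng) -> Candidate:
    """Uniform crossover taking at least one variable from each parent."""
    n = len(parent1.values)
    if n != len(parent2.values):
        raise ValueError("parents live in different spaces")
    take_first = rng.random(n) < 0.5
    differing = [k for k in range(n) if parent1.values[k] != parent2.values[k]]
    if differing:
        if all(take_first[k] for k in differing) and take_first.all():
            take_first[differing[rng.integers(len(differing))]] = False
        elif not any(take_first[k] for k in differing) and not take_first.any():
            take_first[differing[rng.integers(len(differing))]] = True
    values = [p1 if t else p2
              for t, p1, p2 in zip(take_first, parent1.values, parent2.values)]
    return Candidate(values, provenance="crossover")


def _rank_weights(size: int) -> np.ndarray:
    w = np.arange(size, 0, -1, dtype=float)
    return w / w.sum()


def next_generation(population, space: ParameterSpace, config: GAConfig, rng,
                    objective, mutation_strength=None, mutation_rate=None):
    """One generation: elites, mutants, crossover offspring, fresh randoms.

    Composition counts come from the config fractions by largest-remainder
    apportionment; elites are copied unchanged, so the best fitness never
    decreases.
    """
    if config.gen_size < 2:
        raise ValueError("gen_size must be at least 2")
    if len(population) != config.gen_size:
        raise ValueError("population size must equal gen_size")
    if not all(c.evaluated for c in population):
        raise ValueError("population must be fully evaluated")
    strength = config.mutation_strength if mutation_strength is None else mutation_strength
    rate = config.mutation_rate if mutation_rate is None else mutation_rate
    return _step(population, space, config, rng, objective, strength, rate)


def optimize(objective, space: ParameterSpace, config: GAConfig, rng=None,
             seed: int | None = None, initial_population=None) -> OptimizeResult:
    """Run the genetic algorithm until the stop criterion fires.

    ``initial_population`` (a fully formed generation of evaluated
    candidates) replaces the initial design when given; the structure-ladder
    pipeline uses it to carry incumbents between stages.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    wrapped = objective if isinstance(objective, CachingObjective) else \
        CachingObjective(objective)
    if initial_population is not None:
        if len(initial_population) != config.gen_size:
            raise ValueError("initial population size must equal gen_size")
        population = _sorted_population(list(initial_population))
    else:
        population = initial_design(space, config, rng, wrapped)
    best = population[0]
    trace = [best.fitness]
    strength = config.mutation_strength
    rate = config.mutation_rate
    no_improve = 0
    termination = "no_improvement"
    while True:
        if no_improve >= config.stop_iterations:
            termination = "no_improvement"
            break
        if config.eval_budget is not None:
            max_new = config.gen_size - composition_counts(
                config.fractions, config.gen_size)[0]
            if wrapped.calls + max_new > config.eval_budget:
                termination = "eval_budget"
                break
        population = _step(population, space, config, rng, wrapped,
                           strength, rate)
        new_best = population[0]
        improved = new_best.fitness > best.fitness
        if improved:
            best = new_best
            no_improve = 0
        else:
            no_improve += 1
        strength = adapt(strength, config.const_mutation_strength, improved)
        rate = adapt(rate, config.const_mutation_rate, improved)
        trace.append(best.fitness)
    return OptimizeResult(best=best, trace=trace, evaluations=wrapped.calls,
                          seed=seed, termination=termination,
                          population=population,
                          mutation_strength=strength, mutation_rate=rate)


def _step(population, space, config, rng, objective, strength, rate):
    n_el, n_mut, n_cross, n_rand = composition_counts(
        config.fractions, config.gen_size)
    weights = _rank_weights(len(population))
    new = []
    for c in population[:n_el]:
        new.append(Candidate(c.values, fitness=c.fitness, provenance="elite"))
    for _ in range(n_mut):
        parent = population[rng.choice(len(population), p=weights)]
        child = mutate(parent, space, strength, rate, rng)
        child.fitness = objective(child.values)
        new.append(child)
    for _ in range(n_cross):
        if len(population) >= 2:
            i, j = rng.choice(len(population), size=2, replace=False, p=weights)
        else:
            i = j = 0
        child = crossover(population[i], population[j], rng)
        child.fitness = objective(child.values)
        new.append(child)
    for _ in range(n_rand):
        child = Candidate(space.sample(rng), provenance="random")
        child.fitness = objective(child.values)
        new.append(child)
    return _sorted_population(new)


def adapt(value: float, const: float, improved: bool) -> float:
    """One-fifth-rule update of a mutation hyperparameter, clipped to (1e-4, 1]."""
    if not 1.0 <= const <= 2.0:
        raise ValueError("adaptation constant must lie in [1, 2]")
    out = value * const if improved else value / const ** 0.25
    return min(max(out, 1e-4), 1.0)
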