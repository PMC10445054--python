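"""Model/Results interface for demographic inference from an AFS.

:class:`DemographicModel` binds an observed spectrum to a model template
(parameter space plus decoding recipe) and the physical constants needed for
unit translation.  ``fit`` runs seeded genetic-algorithm searches followed by
a derivative-free polish and returns a :class:`DemographicResults` carrying
the best history in both unit systems, the composite log-likelihood, traces
and evaluation counts.  ``fit_ladder`` climbs a model-structure ladder,
re-seeding each stage with likelihood-preserving transforms of the
incumbents.

The module also houses the run-comparison protocol: nested likelihood-ratio
tests, the median/quartile better-worse-incomparable classification and the
speedup / restart-budget arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.stats

from . import io as dio
from .demography import (DemographicHistory, ModelStructure, ModelTemplate,
                         ParameterSpace, UnitScaling, increase_structure,
                         scale_units)
from .engine import EngineSettings, expected_afs
from .ga import (CachingObjective, Candidate, GAConfig, composition_counts,
                 optimize)
from .spectrum import AFS, fold as fold_afs, optimal_theta, poisson_loglik

__all__ = [
    "DemographicModel", "DemographicResults", "RunStats",
    "fit_fixed_structure", "run_inference", "local_polish",
    "lrt_nested", "compare_configurations", "speedup", "restart_budget",
]


class DemographicModel:
    """A demographic-history model bound to an observed frequency spectrum."""

    def __init__(self, data: AFS, template: ModelTemplate,
                 scaling: UnitScaling, settings: EngineSettings | None = None,
                 search_settings: EngineSettings | None = None):
        n_pops_data = data.ndim
        n_pops_model = template.structure.n_pops
        if n_pops_data != n_pops_model:
            raise ValueError(
                f"data has {n_pops_data} population(s) but the model "
                f"describes {n_pops_model}")
        self.data = data
        self.template = template
        self.scaling = scaling
        # reporting/polish settings: adaptive stiff integration, no padding
        # (likelihood comparisons use spectra computed by the same map)
        self.settings = settings or EngineSettings(rtol=1e-6, atol=1e-10,
                                                   corner_padding=0,
                                                   max_rhs_calls=8_000)
        # bulk-search settings: the fixed-step propagator has bounded cost
        # per candidate regardless of stiffness; its small discretization
        # bias is removed by the polish stage
        self.search_settings = search_settings or EngineSettings(
            method="fixed_step", corner_padding=0)

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_fs(cls, path, template, scaling, **kw) -> "DemographicModel":
        return cls(dio.read_fs(path), template, scaling, **kw)

    @classmethod
    def from_vcf(cls, vcf_path, popmap, template, scaling, sample_sizes=None,
                 folded=False, **kw) -> "DemographicModel":
        data = dio.afs_from_vcf(vcf_path, popmap, sample_sizes=sample_sizes,
                                folded=folded)
        return cls(data, template, scaling, **kw)

    # -- likelihood -------------------------------------------------------
    def expected(self, values, settings: EngineSettings | None = None) -> AFS:
        """Model spectrum for a parameter vector, matched to the data."""
        settings = settings or self.settings
        history = self.template.decode(values)
        model = expected_afs(history, self.data.sample_sizes, self.scaling,
                             settings)
        if settings.theta_mode == "optimal_scaling":
            folded_model = fold_afs(model) if self.data.folded else model
            model = model * optimal_theta(folded_model, self.data)
        if self.data.folded:
            model = fold_afs(model)
        return model

    def loglik(self, values, settings: EngineSettings | None = None) -> float:
        try:
            return poisson_loglik(self.expected(values, settings), self.data)
        except (RuntimeError, FloatingPointError):
            return float("-inf")

    def _search_loglik(self, values) -> float:
        return self.loglik(values, self.search_settings)

    def theta(self, values) -> float:
        history = self.template.decode(values)
        if self.settings.theta_mode == "fixed_theta0":
            return self.scaling.theta0(history.N_anc)
        model = expected_afs(history, self.data.sample_sizes, self.scaling,
                             self.settings)
        if self.data.folded:
            model = fold_afs(model)
        return optimal_theta(model, self.data)

    # -- fitting ----------------------------------------------------------
    def fit(self, n_runs: int = 1, seeds=None, ga_config: GAConfig | None = None,
            polish: bool = True) -> "DemographicResults":
        """Independent seeded GA runs at fixed structure; best run polished."""
        ga_config = ga_config or GAConfig.new_default()
        seeds = _resolve_seeds(seeds, n_runs)
        runs = []
        ga_evals = 0
        for seed in seeds:
            # one objective per run: runs are independent and each gets the
            # full evaluation budget
            objective = CachingObjective(self._search_loglik)
            runs.append(optimize(objective, self.template.space, ga_config,
                                 seed=seed))
            ga_evals += objective.calls
        best = self._refine(max(runs, key=lambda r: r.best.fitness).best,
                            polish)
        return DemographicResults(
            model=self, template=self.template, best=best,
            runs=runs, seeds=list(seeds),
            evaluations=ga_evals + best.polish_evals,
            ga_config=ga_config)

    def _refine(self, candidate: Candidate, polish: bool) -> Candidate:
        """Re-score the search winner with the reporting settings and polish.

        Polish runs in two phases: a simplex pass on the bounded fixed-step
        surface to close most of the distance cheaply, then a pass on the
        reporting surface where the adaptive integrator is fast.
        """
        fitness = self.loglik(list(candidate.values))
        best = Candidate(candidate.values, fitness=fitness,
                         provenance=candidate.provenance)
        best.polish_evals = 0
        if polish:
            v1, _, c1 = local_polish(list(best.values), self.template.space,
                                     self._search_loglik)
            f1 = self.loglik(v1)
            start = v1 if f1 >= best.fitness else list(best.values)
            v2, f2, c2 = local_polish(start, self.template.space, self.loglik)
            if f2 >= best.fitness:
                best = Candidate(v2, fitness=f2, provenance="polish")
            best.polish_evals = c1 + c2
        return best

    def fit_ladder(self, final_structure, n_runs: int = 1, seeds=None,
                   ga_config: GAConfig | None = None,
                   polish: bool = True) -> "DemographicResults":
        """Climb the structure ladder from the template's structure to final.

        One GA stage per increment of the leftmost component still below its
        final count; incumbents are transformed so each stage starts at the
        likelihood reached by the previous one.
        """
        if isinstance(final_structure, ModelStructure):
            final = final_structure
        else:
            final = ModelStructure(tuple(final_structure))
        if not ModelStructure(self.template.structure.counts) <= final:
            raise ValueError("initial structure must be <= final, componentwise")
        ga_config = ga_config or GAConfig.new_default()
        seeds = _resolve_seeds(seeds, n_runs)
        stage_results = []
        template = self.template
        total_evals = 0
        per_run_pop = [None] * len(seeds)
        structure = self.template.structure
        stage = 0
        while True:
            stage += 1
            model = DemographicModel(self.data, template, self.scaling,
                                     self.settings, self.search_settings)
            stage_runs = []
            for k, seed in enumerate(seeds):
                objective = CachingObjective(model._search_loglik)
                rng = np.random.default_rng(_stage_seed(seed, stage))
                init = None
                if per_run_pop[k] is not None:
                    init = _reseed_population(per_run_pop[k], template,
                                              ga_config, rng, objective)
                stage_runs.append(optimize(objective, template.space, ga_config,
                                           rng=rng, initial_population=init))
                total_evals += objective.calls
            stage_results.append((template, stage_runs))
            counts = list(structure.counts)
            final_counts = list(final.counts)
            component = next((i for i, (c, f) in
                              enumerate(zip(counts, final_counts)) if c < f), None)
            if component is None:
                break
            # transform each run's population into the incremented space
            new_pops = []
            for r in stage_runs:
                new_template, _ = increase_structure(template, list(r.best.values),
                                                     component)
                transformed = []
                for c in r.population:
                    _, vals = increase_structure(template, list(c.values), component)
                    transformed.append(Candidate(vals, fitness=c.fitness,
                                                 provenance="elite"))
                new_pops.append(transformed)
            template = new_template
            per_run_pop = new_pops
            structure = template.structure

        final_model = DemographicModel(self.data, template, self.scaling,
                                       self.settings, self.search_settings)
        best = final_model._refine(
            max(stage_runs, key=lambda r: r.best.fitness).best, polish)
        return DemographicResults(
            model=final_model, template=template, best=best, runs=stage_runs,
            seeds=list(seeds), evaluations=total_evals + best.polish_evals,
            ga_config=ga_config, stages=stage_results)


def _resolve_seeds(seeds, n_runs):
    if seeds is None:
        seeds = list(range(1, n_runs + 1))
    seeds = [int(s) for s in np.atleast_1d(seeds)]
    return seeds


def _stage_seed(seed, stage):
    return (seed * 1000 + stage) % (2 ** 31)


def _reseed_population(incumbents, template, ga_config, rng, objective):
    """Transformed incumbents fill the elite share; the rest is random."""
    n_el = composition_counts(ga_config.fractions, ga_config.gen_size)[0]
    n_el = max(n_el, 1)
    pop = []
    for c in sorted(incumbents, key=lambda c: -c.fitness)[:n_el]:
        fitness = objective(c.values)
        pop.append(Candidate(c.values, fitness=fitness, provenance="elite"))
    while len(pop) < ga_config.gen_size:
        c = Candidate(template.space.sample(rng), provenance="random")
        c.fitness = objective(c.values)
        pop.append(c)
    return pop


# ---------------------------------------------------------------------------
# local polish


def local_polish(values, space: ParameterSpace, objective, tolerance=1e-10,
                 max_rounds: int = 3, max_calls: int = 6000):
    """Nelder-Mead refinement of the continuous variables.

    Categorical and fixed variables are frozen.  The simplex works in
    unit-box coordinates -- each free variable mapped to [0, 1], on a log10
    scale where the variable is log-scaled -- so parameters whose physical
    magnitudes differ by many orders contribute comparable steps.  The
    returned fitness is never below the input fitness.  Returns
    ``(values, fitness, n_evaluations)``.
    """
    f0 = float(objective(list(values)))
    free = [k for k, v in enumerate(space)
            if v.kind == "continuous" and not v.fixed]
    if not free:
        return list(values), f0, 0

    los, his = [], []
    for k in free:
        v = space.variables[k]
        if v.log_scale:
            los.append(math.log10(v.lower))
            his.append(math.log10(v.upper))
        else:
            los.append(v.lower)
            his.append(v.upper)
    los = np.array(los)
    his = np.array(his)
    span = his - los

    def to_internal(vals):
        raw = []
        for k in free:
            v = space.variables[k]
            x = vals[k]
            raw.append(math.log10(max(x, v.lower if v.lower > 0 else 1e-300))
                       if v.log_scale else x)
        return (np.array(raw) - los) / span

    def from_internal(z):
        raw = los + np.clip(z, 0.0, 1.0) * span
        vals = list(values)
        for r, k in zip(raw, free):
            v = space.variables[k]
            vals[k] = v.clip(10.0 ** r if v.log_scale else r)
        return vals

    calls = 0

    def neg(z):
        nonlocal calls
        calls += 1
        f = objective(from_internal(z))
        return math.inf if f == float("-inf") else -f

    best_vals, best_f = list(values), f0
    z = to_internal(best_vals)
    for _ in range(max_rounds):
        if calls >= max_calls:
            break
        res = scipy.optimize.minimize(
            neg, z, method="Nelder-Mead",
            bounds=[(0.0, 1.0)] * len(free),
            options={"xatol": 1e-9, "fatol": tolerance,
                     "maxfev": min(200 * len(free), max_calls - calls)})
        f = -res.fun if math.isfinite(res.fun) else float("-inf")
        if f > best_f + abs(best_f) * 1e-12:
            best_f = f
            best_vals = from_internal(res.x)
            z = res.x
        else:
            break
    return best_vals, best_f, calls


# ---------------------------------------------------------------------------
# results


@dataclass
class DemographicResults:
    """Estimates, uncertainty surrogates and diagnostics of one inference."""

    model: DemographicModel
    template: ModelTemplate
    best: Candidate
    runs: list
    seeds: list
    evaluations: int
    ga_config: GAConfig
    stages: list | None = None

    def __post_init__(self):
        # the reported candidate descends from the best run's winner; its
        # fitness is the reporting-settings re-evaluation (plus polish)
        if not (math.isfinite(self.best.fitness)
                or self.best.fitness == float("-inf")):
            raise ValueError("reported best fitness must be defined")

    # -- estimates --------------------------------------------------------
    @property
    def params(self) -> dict:
        return self.template.space.as_dict(self.best.values)

    @property
    def loglik(self) -> float:
        return self.best.fitness

    @property
    def history(self) -> DemographicHistory:
        return self.template.decode(list(self.best.values))

    @property
    def history_genetic(self) -> DemographicHistory:
        return scale_units(self.history, self.model.scaling, "to_genetic")

    @property
    def theta(self) -> float:
        return self.model.theta(list(self.best.values))

    def model_afs(self) -> AFS:
        return self.model.expected(list(self.best.values))

    def params_genetic(self) -> dict:
        """Parameter vector re-expressed in genetic units."""
        N_ref = self.history.N_anc
        out = {}
        for name, value in self.params.items():
            if not isinstance(value, str):
                if name.startswith(("N_", "size")):
                    value = value / N_ref
                elif name.startswith("dur"):
                    value = value / (2.0 * N_ref)
                elif name.startswith("m_"):
                    value = value * 2.0 * N_ref
            out[name] = value
        return out

    # -- reporting --------------------------------------------------------
    def report_dict(self) -> dict:
        cfg = self.ga_config
        return {
            "log_likelihood": self.loglik,
            "theta": self.theta,
            "parameters_physical": _jsonable(self.params),
            "parameters_genetic": _jsonable(self.params_genetic()),
            "evaluations": int(self.evaluations),
            "seeds": [int(s) for s in self.seeds],
            "structure": list(self.template.structure.counts),
            "ga_config": {k: getattr(cfg, k) for k in (
                "gen_size", "n_init_const", "p_elitism", "p_mutation",
                "p_crossover", "p_random", "mutation_strength",
                "const_mutation_strength", "mutation_rate",
                "const_mutation_rate")},
            "units": {"sizes": "diploid individuals", "times": "generations",
                      "migration": "per generation"},
        }

    def save_report(self, path):
        dio.write_report(self, path)

    def to_demes(self, path):
        dio.write_history_yaml(self.history, self.model.scaling, path)

    def summary(self) -> str:
        lines = []
        push = lines.append
        push("Demographic inference results")
        push("=" * 64)
        push(f"log-likelihood {self.loglik:>18.6f}    theta {self.theta:>14.6g}")
        push(f"evaluations    {self.evaluations:>18d}    runs  {len(self.runs):>14d}")
        push(f"structure      {str(self.template.structure.counts):>18s}")
        push("-" * 64)
        push(f"{'parameter':<20s} {'physical':>18s} {'genetic':>18s}")
        gen = self.params_genetic()
        for name, value in self.params.items():
            if isinstance(value, str):
                push(f"{name:<20s} {value:>18s} {'-':>18s}")
            else:
                push(f"{name:<20s} {value:>18.6g} {gen[name]:>18.6g}")
        push("=" * 64)
        return "\n".join(lines)


def _jsonable(d):
    return {k: (v if isinstance(v, str) else float(v)) for k, v in d.items()}


# ---------------------------------------------------------------------------
# spec-style pipeline entry points


def fit_fixed_structure(data: AFS, template: ModelTemplate, scaling: UnitScaling,
                        seeds, ga_config=None, settings=None,
                        polish=True) -> DemographicResults:
    model = DemographicModel(data, template, scaling, settings)
    return model.fit(seeds=seeds, ga_config=ga_config, polish=polish)


def run_inference(data: AFS, template: ModelTemplate, scaling: UnitScaling,
                  final_structure, seeds, ga_config=None, settings=None,
                  polish=True) -> DemographicResults:
    model = DemographicModel(data, template, scaling, settings)
    return model.fit_ladder(final_structure, seeds=seeds, ga_config=ga_config,
                            polish=polish)


# ---------------------------------------------------------------------------
# comparison protocol


def lrt_nested(ll_simple: float, ll_complex: float, df: int) -> dict:
    """Likelihood-ratio test of nested models (no Godambe adjustment)."""
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    raw = 2.0 * (ll_complex - ll_simple)
    out = {"statistic": max(raw, 0.0),
           "p_value": float(scipy.stats.chi2.sf(max(raw, 0.0), df)),
           "df": int(df),
           "godambe_adjusted": False}
    if raw < 0:
        out["warning"] = ("complex model has lower log-likelihood than the "
                          "simple model; statistic clamped at 0")
    return out


@dataclass
class RunStats:
    """Final log-likelihoods and evaluation counts of repeated runs."""

    logliks: list
    evaluations: list = field(default_factory=list)

    def __post_init__(self):
        if not len(self.logliks):
            raise ValueError("empty run sample")
        if len(self.evaluations) and \
                len(self.evaluations) != len(self.logliks):
            raise ValueError("per-configuration samples must have equal length")

    def quartiles(self):
        a = np.asarray(self.logliks, dtype=float)
        return tuple(np.quantile(a, (0.25, 0.5, 0.75)))


def compare_configurations(stats_a: RunStats, stats_b: RunStats) -> str:
    """Classify configuration B against A as better/worse/incomparable.

    B is better when its median and both quartiles are strictly higher than
    A's, worse when all three are strictly lower, incomparable otherwise.
    """
    qa = stats_a.quartiles()
    qb = stats_b.quartiles()
    if all(b > a for a, b in zip(qa, qb)):
        return "better"
    if all(b < a for a, b in zip(qa, qb)):
        return "worse"
    return "incomparable"


def speedup(evals_new, evals_default) -> float:
    """Average fraction of evaluations saved by a new configuration."""
    denom = float(np.mean(evals_default))
    if denom == 0:
        raise ValueError("default configuration has zero mean evaluations")
    return 1.0 - float(np.mean(evals_new)) / denom


def restart_budget(y: float, x: float) -> int:
    """Restarts of a single optimizer matching the costlier run: ceil(Y/X)."""
    if x <= 0:
        raise ValueError("single-run evaluation count must be positive")
    return int(math.ceil(y / x))
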