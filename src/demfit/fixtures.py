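"""Packaged ground-truth histories, spectrum samplers and engine oracles.

The two synthetic truths mirror published two-population histories used as
simulation benchmarks: an African/European fruit-fly isolation history with
instantaneous size changes, and a Bornean/Sumatran orangutan
isolation-with-migration history with exponential size changes.  Each
fixture stores the history, the physical constants used for unit
translation, and the free-parameter template that re-fits it; decoding the
template at the stored truth reproduces the history exactly.

Two independent oracles gate the spectrum engine: a closed-form
piecewise-constant single-population SFS built from the coalescent death
chain, and a Monte-Carlo structured-coalescent estimate of expected branch
lengths (backed by msprime/tskit, which shares no numerical code with the
engine's moment ODEs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.special import gammaln

from .demography import (CONSTANT, EXPONENTIAL, LINEAR, C, DemographicHistory,
                         EpochSpec, ModelStructure, ModelTemplate,
                         ParameterSpace, SplitEvent, SplitSpec, UnitScaling, V,
                         Variable)
from .spectrum import AFS

__all__ = [
    "Fixture", "drosophila_truth", "orangutan_truth", "blischak_model",
    "sample_afs_poisson", "piecewise_constant_sfs_oracle", "mc_coalescent_afs",
]


@dataclass
class Fixture:
    """A ground-truth history with its refitting template."""

    name: str
    history: DemographicHistory
    scaling: UnitScaling
    template: ModelTemplate
    truth: dict
    recombination_rate: float | None = None   # documentation only
    identifiability_note: str = ""
    default_sample_sizes: tuple = (10, 10)    # 5 diploids per population

    @property
    def truth_values(self):
        return [self.truth[name] for name in self.template.space.names]


def _size_var(name, fixed=None):
    return Variable(name, "continuous", 1e2, 1e8, log_scale=True,
                    fixed_value=fixed)


def _time_var(name, fixed=None):
    return Variable(name, "continuous", 1.0, 1e7, log_scale=True,
                    fixed_value=fixed)


def _mig_var(name, fixed=None):
    return Variable(name, "continuous", 0.0, 1e-2, fixed_value=fixed)


def drosophila_truth(variant: str = "NOMIG") -> Fixture:
    """Fruit-fly two-population isolation history and its custom template.

    Ancestral population of 1.72 M expands instantly to 8.6 M; the European
    population splits off 158 k generations ago through a 2,200-individual
    bottleneck and expands to 1.075 M after 3,400 generations.  The African
    size is shared across the three most recent epochs (a single expansion),
    giving 7 free parameters; the ``MIG`` variant adds two continuous
    asymmetric migration rates (truth 0) shared by both post-split epochs.
    """
    if variant not in ("NOMIG", "MIG"):
        raise ValueError("variant must be 'NOMIG' or 'MIG'")
    truth = {
        "N_anc": 1_720_600.0,
        "N_AFR": 8_603_000.0,
        "N_EUP0": 2_200.0,
        "N_EUP": 1_075_000.0,
        "dur_pre2": 600_000.0 - 158_000.0,    # expansion to split
        "dur_post1": 158_000.0 - 154_600.0,   # bottleneck
        "dur_post2": 154_600.0,               # expansion to present
    }
    variables = [
        _size_var("N_anc"), _size_var("N_AFR"), _size_var("N_EUP0"),
        _size_var("N_EUP"), _time_var("dur_pre2"), _time_var("dur_post1"),
        _time_var("dur_post2"),
    ]
    mig = None
    if variant == "MIG":
        variables += [_mig_var("m_01"), _mig_var("m_10")]
        truth["m_01"] = 0.0
        truth["m_10"] = 0.0
        mig = [[C(0.0), V("m_01")], [V("m_10"), C(0.0)]]
    template = ModelTemplate(
        structure=ModelStructure((2, 2)),
        space=ParameterSpace(variables),
        n_anc=V("N_anc"),
        pre_epochs=[EpochSpec(V("dur_pre2"), [V("N_AFR")], [C(CONSTANT)])],
        split=SplitSpec("free", child_sizes=[V("N_AFR"), V("N_EUP0")]),
        post_epochs=[
            EpochSpec(V("dur_post1"), [V("N_AFR"), V("N_EUP0")],
                      [C(CONSTANT), C(CONSTANT)], migration=mig),
            EpochSpec(V("dur_post2"), [V("N_AFR"), V("N_EUP")],
                      [C(CONSTANT), C(CONSTANT)], migration=mig),
        ],
        pop_labels=("AFR", "EUR"),
    )
    history = template.decode([truth[n] for n in template.space.names])
    return Fixture(
        name=f"DROS-{variant}",
        history=history,
        scaling=UnitScaling(mu=5.49e-9, L=1.1e8, generation_time=1.0),
        template=template,
        truth=truth,
        recombination_rate=8.4e-9,
        identifiability_note=(
            "The bottleneck size and its short duration are jointly weakly "
            "identified (their ratio dominates the drift it causes); all "
            "other sizes and times are well identified from noise-free data."),
    )


def orangutan_truth(variant: str = "MIG") -> Fixture:
    """Orangutan isolation-with-migration history and its custom template.

    The 17,934-strong ancestral population splits 20,157 generations ago
    into Bornean (population 0) and Sumatran (population 1) populations of
    10,617 and 7,317 (their sum equals the ancestral size, so the history is
    also expressible with a fraction-mode split), which change exponentially
    to 8,805 and 37,661 under continuous asymmetric migration.  Migration is
    parameterized by the per-generation fraction of the receiving population
    replaced: ``m_01`` is received by the Bornean population from the
    Sumatran one.  8 free parameters; the ``NOMIG`` variant fixes both rates
    to 0.
    """
    if variant not in ("NOMIG", "MIG"):
        raise ValueError("variant must be 'NOMIG' or 'MIG'")
    fix = 0.0 if variant == "NOMIG" else None
    truth = {
        "N_anc": 17_934.0,
        "N_split_pop0": 10_617.0,
        "N_split_pop1": 7_317.0,
        "N_post1_pop0": 8_805.0,
        "N_post1_pop1": 37_661.0,
        "m_post1_01": 0.0 if variant == "NOMIG" else 1.10e-5,
        "m_post1_10": 0.0 if variant == "NOMIG" else 0.66e-5,
        "dur_post1": 20_157.0,
    }
    variables = [
        _size_var("N_anc"),
        _size_var("N_split_pop0"), _size_var("N_split_pop1"),
        _size_var("N_post1_pop0"), _size_var("N_post1_pop1"),
        _mig_var("m_post1_01", fixed=fix), _mig_var("m_post1_10", fixed=fix),
        _time_var("dur_post1"),
    ]
    template = ModelTemplate(
        structure=ModelStructure((1, 1)),
        space=ParameterSpace(variables),
        n_anc=V("N_anc"),
        pre_epochs=[],
        split=SplitSpec("free", child_sizes=[V("N_split_pop0"),
                                             V("N_split_pop1")]),
        post_epochs=[EpochSpec(
            V("dur_post1"),
            [V("N_post1_pop0"), V("N_post1_pop1")],
            [C(EXPONENTIAL), C(EXPONENTIAL)],
            migration=[[C(0.0), V("m_post1_01")],
                       [V("m_post1_10"), C(0.0)]])],
        pop_labels=("Bornean", "Sumatran"),
    )
    history = template.decode([truth[n] for n in template.space.names])
    return Fixture(
        name=f"ORAN-{variant}",
        history=history,
        scaling=UnitScaling(mu=1.5e-8, L=2.87e9, generation_time=1.0),
        template=template,
        truth=truth,
        recombination_rate=None,   # chromosome-averaged map in the source data
        identifiability_note=(
            "All 8 parameters are identified from the joint spectrum of 10+10 "
            "haploids with migration included."),
    )


def blischak_model(species: str, with_inbreeding: bool) -> ModelTemplate:
    """Free-parameter templates for the two empirical inbreeding datasets.

    ``puma``: two-population isolation (ancestral size, two constant
    descendant sizes, divergence time, optionally one inbreeding coefficient
    per population).  ``cabbage``: a single population through three constant
    epochs, optionally with one inbreeding coefficient.  The matching
    physical constants are attached as ``template.options['scaling']``.
    """
    if species == "puma":
        variables = [
            _size_var("N_anc"), _size_var("N_post1_pop0"),
            _size_var("N_post1_pop1"), _time_var("dur_post1"),
        ]
        inb = None
        if with_inbreeding:
            variables += [
                Variable("F_pop0", "continuous", 0.0, 1.0),
                Variable("F_pop1", "continuous", 0.0, 1.0),
            ]
            inb = [V("F_pop0"), V("F_pop1")]
        template = ModelTemplate(
            structure=ModelStructure((1, 1)),
            space=ParameterSpace(variables),
            n_anc=V("N_anc"),
            pre_epochs=[],
            split=SplitSpec("free", child_sizes=[V("N_post1_pop0"),
                                                 V("N_post1_pop1")]),
            post_epochs=[EpochSpec(
                V("dur_post1"), [V("N_post1_pop0"), V("N_post1_pop1")],
                [C(CONSTANT), C(CONSTANT)])],
            inbreeding=inb,
            pop_labels=("Texas", "Florida"),
        )
        template.options["scaling"] = UnitScaling(
            mu=2.2e-9, L=2_564_692_624.0, generation_time=3.0)
        return template
    if species == "cabbage":
        variables = [
            _size_var("N_anc"), _size_var("N_pre2"), _size_var("N_pre3"),
            _time_var("dur_pre2"), _time_var("dur_pre3"),
        ]
        inb = None
        if with_inbreeding:
            variables.append(Variable("F_pop0", "continuous", 0.0, 1.0))
            inb = [V("F_pop0")]
        template = ModelTemplate(
            structure=ModelStructure((3,)),
            space=ParameterSpace(variables),
            n_anc=V("N_anc"),
            pre_epochs=[
                EpochSpec(V("dur_pre2"), [V("N_pre2")], [C(CONSTANT)]),
                EpochSpec(V("dur_pre3"), [V("N_pre3")], [C(CONSTANT)]),
            ],
            pop_labels=("cabbage",),
        )
        template.options["scaling"] = UnitScaling(
            mu=1.5e-8, L=411_560_319.0, generation_time=1.0)
        return template
    raise ValueError("species must be 'puma' or 'cabbage'")


# ---------------------------------------------------------------------------
# samplers


def sample_afs_poisson(expected: AFS, rng) -> AFS:
    """Independent Poisson draw per unmasked bin (the random-field model)."""
    data = np.zeros_like(expected.data)
    keep = ~expected.mask
    data[keep] = rng.poisson(expected.data[keep])
    return AFS(data, folded=expected.folded, mask=expected.mask.copy(),
               pop_labels=expected.pop_labels)


# ---------------------------------------------------------------------------
# closed-form oracle


def piecewise_constant_sfs_oracle(sizes, durations, theta0, n,
                                  dynamics=None) -> AFS:
    """Exact expected unfolded SFS for piecewise-constant single-population
    histories, via the coalescent death chain.

    ``sizes[0]`` is the ancestral (reference) size, extending infinitely
    into the past; ``sizes[k]`` (k >= 1) lasts ``durations[k-1]``
    generations, oldest first.  ``theta0`` is ``4 N_ref mu L`` with
    ``N_ref = sizes[0]``.  Shares no code with the engine's moment ODEs:
    expected coalescent waiting times are accumulated with a pure-death
    chain and combined with the exchangeable family-size weights.
    """
    sizes = [float(s) for s in np.atleast_1d(sizes)]
    durations = [float(d) for d in np.atleast_1d(durations)] if durations is not None else []
    if dynamics is not None and any(d != CONSTANT for d in dynamics):
        raise ValueError("the closed-form oracle handles constant dynamics only")
    if len(durations) != len(sizes) - 1:
        raise ValueError("need one duration per non-ancestral epoch")
    N_ref = sizes[0]
    nus = [s / N_ref for s in sizes]
    taus = [d / (2.0 * N_ref) for d in durations]

    # death chain states k = n..2 (state 1 absorbing); rates C(k,2)/nu
    ks = np.arange(n, 1, -1)
    p = np.zeros(len(ks) + 1)
    p[0] = 1.0                      # all n lineages at present
    T = np.zeros(n + 1)             # E[time with k lineages], 2*N_ref gens

    # recent epochs first
    for nu, tau in zip(reversed(nus[1:]), reversed(taus)):
        rates = ks * (ks - 1) / 2.0 / nu
        m = len(ks)
        Q = np.zeros((m + 1, m + 1))
        for i, r in enumerate(rates):
            Q[i, i] = -r
            Q[i + 1, i] = r
        aug = np.zeros((2 * (m + 1), 2 * (m + 1)))
        aug[:m + 1, :m + 1] = Q * tau
        aug[m + 1:, :m + 1] = np.eye(m + 1) * tau
        prop = expm(aug)
        occupancy = prop[m + 1:, :m + 1] @ p
        for i, k in enumerate(ks):
            T[k] += occupancy[i]
        p = prop[:m + 1, :m + 1] @ p

    # infinite ancestral epoch: expected time in k = P(reach k) * nu / C(k,2)
    nu_anc = nus[0]
    for i, k in enumerate(ks):
        reach = p[:i + 1].sum()
        T[k] += reach * nu_anc / (k * (k - 1) / 2.0)

    lc = lambda a, b: gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
    xi = np.zeros(n + 1)
    for b in range(1, n):
        acc = 0.0
        for k in range(2, n - b + 2):
            w = math.exp(lc(n - b - 1, k - 2) - lc(n - 1, k - 1))
            acc += k * T[k] * w
        xi[b] = 0.5 * theta0 * acc
    return AFS(xi, folded=False)


# ---------------------------------------------------------------------------
# Monte-Carlo structured-coalescent oracle


def _history_to_msprime(history: DemographicHistory, scaling: UnitScaling,
                        linear_steps: int = 64):
    """Translate a physical-unit history into an msprime Demography.

    Linear size trajectories are approximated by a ``linear_steps``-piece
    constant staircase (msprime supports constant and exponential only).
    """
    import msprime

    if history.units != "physical":
        raise ValueError("the oracle expects physical units")
    split = history.split()
    epochs = history.epochs()
    total = history.total_time()
    labels = list(history.pop_labels or (
        ("pop0", "pop1") if history.n_pops == 2 else ("pop0",)))

    dem = msprime.Demography()
    if split is None:
        dem.add_population(name=labels[0], initial_size=history.N_anc)
        pops = [labels[0]]
        anc = labels[0]
    else:
        for l in labels:
            dem.add_population(name=l, initial_size=1000.0)
        dem.add_population(name="anc", initial_size=history.N_anc)
        pops = labels
        anc = "anc"

    split_index = history.events.index(split) if split is not None else None
    t_split = (sum(e.duration for e in history.events[split_index + 1:])
               if split is not None else None)

    # In msprime's backward-time semantics a parameter change at time t
    # applies to all older times until the next change, and exponential
    # growth decays going back from the event time -- exactly one event
    # batch at each epoch's recent boundary reproduces the history.
    size_events = []   # (time_bp, pop, initial_size, growth_rate)
    mig_events = []    # (time_bp, dest, source, rate)  (our convention)

    def add_piece(pop, t_lo, t_hi, start, end, dyn):
        if dyn == CONSTANT or start == end:
            size_events.append((t_lo, pop, end, 0.0))
        elif dyn == EXPONENTIAL:
            alpha = math.log(end / start) / (t_hi - t_lo)
            size_events.append((t_lo, pop, end, alpha))
        elif dyn == LINEAR:
            edges = np.linspace(t_lo, t_hi, linear_steps + 1)
            for a, b in zip(edges[:-1], edges[1:]):
                mid = 0.5 * (a + b)
                frac = (t_hi - mid) / (t_hi - t_lo)
                size_events.append((a, pop, start + (end - start) * frac, 0.0))

    t = total
    sizes = (history.N_anc,)
    post = False
    for ev in history.events:
        if isinstance(ev, SplitEvent):
            post = True
            sizes = ev.child_start_sizes(sizes[ev.parent_index])
            continue
        t_hi, t_lo = t, t - ev.duration
        t = t_lo
        start = sizes
        if not post:
            add_piece(anc, t_lo, t_hi, start[0], ev.end_sizes[0], ev.dynamics[0])
        else:
            for p in range(2):
                add_piece(pops[p], t_lo, t_hi, start[p], ev.end_sizes[p],
                          ev.dynamics[p])
            for dest in range(2):
                for source in range(2):
                    if dest != source:
                        rate = (ev.migration[dest][source]
                                if ev.migration is not None else 0.0)
                        mig_events.append((t_lo, pops[dest], pops[source], rate))
        sizes = ev.end_sizes

    if (split is None and epochs) or (split is not None and epochs[:split_index]):
        size_events.append((total, anc, history.N_anc, 0.0))

    for time_bp, pop, size, growth in size_events:
        if time_bp == 0.0:
            dem[pop].initial_size = size
            dem[pop].growth_rate = growth
        else:
            dem.add_population_parameters_change(
                time=time_bp, population=pop, initial_size=size,
                growth_rate=growth)
    for time_bp, dest, source, rate in mig_events:
        # msprime's backward "source" is the receiving deme of forward
        # migration, i.e. our dest
        if time_bp == 0.0:
            dem.set_migration_rate(dest, source, rate)
        else:
            dem.add_migration_rate_change(time=time_bp, rate=rate,
                                          source=dest, dest=source)
    if split is not None:
        dem.add_population_split(time=t_split, derived=pops, ancestral=anc)
    dem.sort_events()
    return dem, pops if split is not None else [anc]


def mc_coalescent_afs(history: DemographicHistory, sample_sizes, replicates,
                      rng, scaling: UnitScaling):
    """Monte-Carlo expected AFS with per-bin standard errors.

    Simulates independent non-recombining genealogies backward in time under
    the history (piecewise sizes, split, continuous migration), accumulates
    the expected branch length subtending each joint derived-count class and
    multiplies by the mutation intensity ``mu * L``.
    """
    import msprime

    if history.selection_gamma is not None:
        raise ValueError("selection is unsupported")
    sample_sizes = tuple(int(n) for n in np.atleast_1d(sample_sizes))
    dem, pops = _history_to_msprime(history, scaling)
    # sizes are diploid individuals; sample n haploid genomes per population
    samples = [msprime.SampleSet(n, population=p, ploidy=1)
               for p, n in zip(pops, sample_sizes)]
    seed = int(rng.integers(1, 2 ** 31 - 1))
    shape = tuple(n + 1 for n in sample_sizes)
    total = np.zeros(shape)
    total_sq = np.zeros(shape)
    count = 0
    reps = msprime.sim_ancestry(samples=samples, demography=dem,
                                num_replicates=int(replicates),
                                random_seed=seed)
    for ts in reps:
        sets = [ts.samples(population=k) for k in range(len(sample_sizes))]
        a = ts.allele_frequency_spectrum(sample_sets=sets, mode="branch",
                                         polarised=True, span_normalise=True)
        total += a
        total_sq += a * a
        count += 1
    mean = total / count
    var = np.maximum(total_sq / count - mean ** 2, 0.0)
    se = np.sqrt(var / count)
    intensity = scaling.mu * scaling.L
    return (AFS(mean * intensity, folded=False, pop_labels=history.pop_labels),
            se * intensity)


# ---------------------------------------------------------------------------
# noise-free self-recovery experiment


def refit_noise_free(fixture: Fixture, sample_sizes=None, seeds=(1, 2, 3, 4),
                     ga_config=None, settings=None, polish=True):
    """Refit a fixture's template to its own noise-free expected spectrum.

    The data spectrum is generated with the same engine settings used for
    fitting, so the likelihood optimum sits exactly at the stored truth and
    the experiment isolates optimizer quality.  The evaluation budget
    follows the 200-evaluations-per-parameter rule.  Returns the fitted
    :class:`~demfit.model.DemographicResults`.
    """
    from .engine import EngineSettings, expected_afs
    from .ga import GAConfig
    from .model import DemographicModel

    sample_sizes = sample_sizes or fixture.default_sample_sizes
    settings = settings or EngineSettings(rtol=1e-6, atol=1e-10,
                                          corner_padding=0)
    data = expected_afs(fixture.history, sample_sizes, fixture.scaling,
                        settings)
    if ga_config is None:
        budget = 200 * fixture.template.space.dimension
        ga_config = GAConfig.new_default(eval_budget=budget)
    model = DemographicModel(data, fixture.template, fixture.scaling, settings)
    return model.fit(seeds=list(seeds), ga_config=ga_config, polish=polish)
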