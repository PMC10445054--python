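"""Demographic histories, model structures and parameter spaces.

A demographic history is an ordered sequence (oldest to newest) of epochs and
at most one population split.  Histories start from an ancestral population of
diploid size ``N_anc`` at neutral equilibrium.  Each epoch carries a duration,
per-population end sizes, a per-population size dynamic (constant, linear or
exponential interpolation from the epoch's start sizes) and, after a split,
per-ordered-pair continuous migration rates.

A *model structure* ``(s1,)`` or ``(s1, s2)`` counts the epochs before and
after the split.  :func:`build_space` turns a structure plus model options
into a :class:`ModelTemplate` -- a parameter space (mixed continuous and
categorical variables) together with the bindings needed to decode a value
vector into a :class:`DemographicHistory`.  Custom templates with tied or
fixed parameters are built from the same primitives (see
:mod:`demfit.fixtures`).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CONSTANT", "LINEAR", "EXPONENTIAL", "DYNAMICS",
    "Epoch", "SplitEvent", "DemographicHistory", "ModelStructure",
    "Variable", "ParameterSpace", "UnitScaling",
    "V", "C", "EpochSpec", "SplitSpec", "ModelTemplate",
    "size_trajectory", "scale_units", "build_space", "decode", "encode",
    "increase_structure",
]

CONSTANT = "constant"
LINEAR = "linear"
EXPONENTIAL = "exponential"
DYNAMICS = (CONSTANT, LINEAR, EXPONENTIAL)

#: default physical-unit bounds; spans every value in the packaged truths
DEFAULT_BOUNDS = {
    "size": (1e2, 1e8),          # diploid individuals, log-uniform
    "duration": (1.0, 1e7),      # generations, uniform
    "migration": (0.0, 1e-2),    # per generation, uniform
    "fraction": (1e-3, 1.0 - 1e-3),
    "inbreeding": (0.0, 1.0),
}


# ---------------------------------------------------------------------------
# history containers


@dataclass
class Epoch:
    """One time interval of a demographic history.

    ``end_sizes`` are the sizes reached at the (more recent) end of the
    epoch.  Start sizes are inherited from the previous event; under the
    constant dynamic the population jumps to ``end_sizes`` instantly at the
    epoch start, under linear/exponential dynamics it interpolates from the
    inherited start sizes.
    """

    duration: float
    end_sizes: tuple
    dynamics: tuple
    migration: tuple | None = None   # migration[dest][source], per generation
    symmetric: bool = False
    migration_mask: tuple | None = None  # True = rate enabled

    def __post_init__(self):
        self.end_sizes = tuple(float(s) for s in self.end_sizes)
        self.dynamics = tuple(self.dynamics)
        if len(self.end_sizes) != len(self.dynamics):
            raise ValueError("one dynamic per population required")
        for d in self.dynamics:
            if d not in DYNAMICS:
                raise ValueError(f"unknown dynamic {d!r}")
        for s in self.end_sizes:
            if not s > 0:
                raise ValueError("population sizes must be positive")
        if self.duration < 0 or not math.isfinite(self.duration):
            raise ValueError("epoch duration must be finite and >= 0")
        npop = len(self.end_sizes)
        if self.migration is not None:
            m = tuple(tuple(float(x) for x in row) for row in self.migration)
            if len(m) != npop or any(len(r) != npop for r in m):
                raise ValueError("migration matrix shape mismatch")
            if self.migration_mask is None:
                mask = tuple(tuple(i != j for j in range(npop)) for i in range(npop))
            else:
                mask = tuple(tuple(bool(x) for x in row) for row in self.migration_mask)
            for i in range(npop):
                for j in range(npop):
                    if i == j:
                        continue
                    if m[i][j] < 0:
                        raise ValueError("migration rates must be >= 0")
                    if not mask[i][j] and m[i][j] != 0.0:
                        raise ValueError("masked migration rate must be exactly 0")
            if self.symmetric:
                if npop == 2 and mask[0][1] != mask[1][0]:
                    raise ValueError("migration mask inconsistent with symmetric flag")
                if npop == 2 and mask[0][1] and m[0][1] != m[1][0]:
                    raise ValueError("symmetric flag requires equal rates")
            self.migration = m
            self.migration_mask = mask

    @property
    def n_pops(self) -> int:
        return len(self.end_sizes)


@dataclass
class SplitEvent:
    """Division of one population into two.

    ``fraction`` mode conserves size: the children start at ``s * N_parent``
    and ``(1 - s) * N_parent``.  ``free`` mode assigns independent start
    sizes to the children.
    """

    parent_index: int = 0
    mode: str = "fraction"
    fraction: float | None = None
    child_sizes: tuple | None = None

    def __post_init__(self):
        if self.mode not in ("fraction", "free"):
            raise ValueError("split mode must be 'fraction' or 'free'")
        if self.mode == "fraction":
            if self.fraction is None or not (0.0 < self.fraction < 1.0):
                raise ValueError("split fraction must lie in (0, 1)")
        else:
            if self.child_sizes is None or len(self.child_sizes) != 2:
                raise ValueError("free split requires two child sizes")
            self.child_sizes = tuple(float(s) for s in self.child_sizes)

    def child_start_sizes(self, parent_size: float) -> tuple:
        if self.mode == "fraction":
            # twice-subtracted split so the sum conserves the parent size
            # exactly in floating point
            second = parent_size - self.fraction * parent_size
            first = parent_size - second
            return (first, second)
        return self.child_sizes


@dataclass
class DemographicHistory:
    """Ordered demographic history for one or two populations."""

    N_anc: float
    events: list
    inbreeding: tuple | None = None
    selection_gamma: float | None = None
    dominance_h: float | None = None
    units: str = "physical"
    N_ref: float | None = None
    pop_labels: tuple | None = None

    def __post_init__(self):
        if not self.N_anc > 0:
            raise ValueError("ancestral size must be positive")
        n_splits = sum(isinstance(e, SplitEvent) for e in self.events)
        if n_splits > 1:
            raise ValueError("at most one split event is supported")
        npop = 1
        seen_split = False
        for ev in self.events:
            if isinstance(ev, SplitEvent):
                seen_split = True
                npop = 2
            elif isinstance(ev, Epoch):
                if ev.n_pops != npop:
                    raise ValueError("population count changed without a split")
            else:
                raise TypeError(f"unknown event {ev!r}")
        self._seen_split = seen_split
        if self.inbreeding is not None:
            self.inbreeding = tuple(float(f) for f in self.inbreeding)
            for f in self.inbreeding:
                if not 0.0 <= f <= 1.0:
                    raise ValueError("inbreeding coefficients must lie in [0, 1]")

    @property
    def n_pops(self) -> int:
        return 2 if self._seen_split else 1

    def epochs(self):
        return [e for e in self.events if isinstance(e, Epoch)]

    def split(self):
        for e in self.events:
            if isinstance(e, SplitEvent):
                return e
        return None

    def start_sizes_of(self, index: int) -> tuple:
        """Sizes at the older boundary of ``events[index]`` (an Epoch)."""
        sizes = (self.N_anc,)
        for k, ev in enumerate(self.events):
            if k == index:
                return sizes
            if isinstance(ev, SplitEvent):
                sizes = ev.child_start_sizes(sizes[ev.parent_index])
            else:
                sizes = size_trajectory(ev, sizes, ev.duration)
        raise IndexError(index)

    def total_time(self) -> float:
        return sum(e.duration for e in self.epochs())


@dataclass(frozen=True)
class ModelStructure:
    counts: tuple

    def __post_init__(self):
        counts = tuple(int(c) for c in self.counts)
        if len(counts) not in (1, 2) or any(c < 1 for c in counts):
            raise ValueError("structure must be (s1,) or (s1, s2) with counts >= 1")
        object.__setattr__(self, "counts", counts)

    @property
    def n_pops(self) -> int:
        return len(self.counts)

    def __le__(self, other) -> bool:
        return len(self.counts) == len(other.counts) and all(
            a <= b for a, b in zip(self.counts, other.counts)
        )


# ---------------------------------------------------------------------------
# parameter space


@dataclass
class Variable:
    name: str
    kind: str = "continuous"          # or "categorical"
    lower: float | None = None
    upper: float | None = None
    categories: tuple | None = None
    log_scale: bool = False
    fixed_value: object = None

    def __post_init__(self):
        if self.kind == "continuous":
            if self.lower is None or self.upper is None:
                raise ValueError(f"{self.name}: continuous variable needs bounds")
            if not (math.isfinite(self.lower) and math.isfinite(self.upper)
                    and self.lower < self.upper):
                raise ValueError(f"{self.name}: bounds must be finite with lower < upper")
        elif self.kind == "categorical":
            if not self.categories:
                raise ValueError(f"{self.name}: categorical variable needs categories")
            self.categories = tuple(self.categories)
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")

    @property
    def fixed(self) -> bool:
        return self.fixed_value is not None

    def contains(self, value) -> bool:
        if self.kind == "categorical":
            return value in self.categories
        return self.lower <= value <= self.upper

    def sample(self, rng) -> object:
        if self.fixed:
            return self.fixed_value
        if self.kind == "categorical":
            return self.categories[rng.integers(len(self.categories))]
        if self.log_scale:
            return float(np.exp(rng.uniform(np.log(self.lower), np.log(self.upper))))
        return float(rng.uniform(self.lower, self.upper))

    def clip(self, value: float) -> float:
        return float(min(max(value, self.lower), self.upper))


class ParameterSpace:
    """Ordered list of mixed continuous/categorical variables."""

    def __init__(self, variables):
        self.variables = list(variables)
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        self._index = {v.name: k for k, v in enumerate(self.variables)}

    def __len__(self):
        return len(self.variables)

    def __iter__(self):
        return iter(self.variables)

    def __getitem__(self, name):
        return self.variables[self._index[name]]

    @property
    def names(self):
        return [v.name for v in self.variables]

    @property
    def dimension(self) -> int:
        """Number of free (non-fixed) variables."""
        return sum(not v.fixed for v in self.variables)

    def sample(self, rng):
        return [v.sample(rng) for v in self.variables]

    def validate(self, values):
        if len(values) != len(self.variables):
            raise ValueError(
                f"value vector length {len(values)} != space arity {len(self.variables)}")
        for v, x in zip(self.variables, values):
            if v.fixed and x != v.fixed_value:
                raise ValueError(f"variable {v.name} is fixed to {v.fixed_value}")
            if not v.contains(x):
                raise ValueError(f"value {x!r} out of bounds for variable {v.name}")

    def as_dict(self, values):
        return dict(zip(self.names, values))


# ---------------------------------------------------------------------------
# unit scaling


@dataclass(frozen=True)
class UnitScaling:
    """Physical constants used to translate between unit systems.

    ``mu`` is the mutation rate per base per generation, ``L`` the assayed
    sequence length in bp and ``generation_time`` the generation time in
    years.  ``theta0(N)`` is always recomputed as ``4 N mu L``.
    """

    mu: float
    L: float
    generation_time: float = 1.0

    def __post_init__(self):
        if self.mu <= 0 or self.L <= 0 or self.generation_time <= 0:
            raise ValueError("scaling constants must be positive")

    def theta0(self, N_anc: float) -> float:
        return 4.0 * N_anc * self.mu * self.L

    def generations_to_years(self, g: float) -> float:
        return g * self.generation_time

    def years_to_generations(self, y: float) -> float:
        return y / self.generation_time


def size_trajectory(epoch: Epoch, start_sizes, t: float):
    """Per-population size at time ``t`` inside an epoch (0 at the old end)."""
    T = epoch.duration
    if not 0.0 <= t <= T and T > 0:
        raise ValueError("t must lie within [0, duration]")
    out = []
    for p, dyn in enumerate(epoch.dynamics):
        s0, s1 = float(start_sizes[p]), epoch.end_sizes[p]
        if dyn == CONSTANT:
            out.append(s1)
            continue
        if T == 0.0:
            if s0 != s1:
                raise ValueError(
                    f"{dyn} interpolation over zero duration with start != end")
            out.append(s1)
            continue
        if t == T:
            out.append(s1)
        elif dyn == LINEAR:
            out.append(s0 + (s1 - s0) * t / T)
        else:  # exponential
            out.append(s0 * (s1 / s0) ** (t / T))
    return tuple(out)


def scale_units(history: DemographicHistory, scaling: UnitScaling,
                direction: str) -> DemographicHistory:
    """Translate a history between physical and genetic units.

    Genetic units: sizes relative to ``N_ref`` (the physical ancestral size),
    times in units of ``2 N_ref`` generations, migration rates multiplied by
    ``2 N_ref``.  The reference size is retained on the result so the
    translation round-trips.
    """
    if direction not in ("to_genetic", "to_physical"):
        raise ValueError("direction must be 'to_genetic' or 'to_physical'")
    if direction == "to_genetic":
        if history.units != "physical":
            raise ValueError("history is already in genetic units")
        N_ref = history.N_anc
        if not N_ref > 0:
            raise ValueError("non-positive reference size")
        f_size, f_time, f_mig = 1.0 / N_ref, 1.0 / (2.0 * N_ref), 2.0 * N_ref
        new_units, new_ref = "genetic", N_ref
    else:
        if history.units != "genetic":
            raise ValueError("history is already in physical units")
        N_ref = history.N_ref
        if N_ref is None or not N_ref > 0:
            raise ValueError("genetic-unit history lacks a positive reference size")
        f_size, f_time, f_mig = N_ref, 2.0 * N_ref, 1.0 / (2.0 * N_ref)
        new_units, new_ref = "physical", None

    events = []
    for ev in history.events:
        if isinstance(ev, SplitEvent):
            if ev.mode == "free":
                events.append(replace(ev, child_sizes=tuple(
                    s * f_size for s in ev.child_sizes)))
            else:
                events.append(copy.deepcopy(ev))
        else:
            mig = None
            if ev.migration is not None:
                mig = tuple(tuple(x * f_mig for x in row) for row in ev.migration)
            events.append(Epoch(
                duration=ev.duration * f_time,
                end_sizes=tuple(s * f_size for s in ev.end_sizes),
                dynamics=ev.dynamics,
                migration=mig,
                symmetric=ev.symmetric,
                migration_mask=ev.migration_mask,
            ))
    return DemographicHistory(
        N_anc=history.N_anc * f_size,
        events=events,
        inbreeding=history.inbreeding,
        selection_gamma=history.selection_gamma,
        dominance_h=history.dominance_h,
        units=new_units,
        N_ref=new_ref,
        pop_labels=history.pop_labels,
    )


# ---------------------------------------------------------------------------
# templates: bindings from variables to history slots


class V:
    """Reference to a named variable."""

    __slots__ = ("name",)

    def __init__(self, name):
        self.name = name

    def resolve(self, values):
        return values[self.name]

    def __repr__(self):
        return f"V({self.name!r})"


class C:
    """A constant slot value."""

    __slots__ = ("value",)

    def __init__(self, value):
        self.value = value

    def resolve(self, values):
        return self.value

    def __repr__(self):
        return f"C({self.value!r})"


@dataclass
class EpochSpec:
    duration: object
    end_sizes: list
    dynamics: list
    migration: list | None = None    # matrix of refs, diagonal ignored
    symmetric: bool = False
    migration_mask: tuple | None = None


@dataclass
class SplitSpec:
    mode: str = "fraction"
    fraction: object = None
    child_sizes: list | None = None


class ModelTemplate:
    """A parameter space plus the recipe decoding value vectors to histories.

    Templates may tie one variable to several history slots (e.g. a constant
    population size shared across epochs) and may fix variables to constants.
    """

    def __init__(self, structure: ModelStructure, space: ParameterSpace,
                 n_anc, pre_epochs, split=None, post_epochs=(),
                 inbreeding=None, pop_labels=None, options=None):
        self.structure = structure
        self.space = space
        self.n_anc = n_anc
        self.pre_epochs = list(pre_epochs)
        self.split = split
        self.post_epochs = list(post_epochs)
        self.inbreeding = inbreeding
        self.pop_labels = pop_labels
        self.options = dict(options or {})

    # -- decode -----------------------------------------------------------
    def decode(self, values) -> DemographicHistory:
        self.space.validate(values)
        vals = self.space.as_dict(values)
        events = []
        for spec in self.pre_epochs:
            events.append(self._epoch_from_spec(spec, vals))
        if self.split is not None:
            if self.split.mode == "fraction":
                events.append(SplitEvent(mode="fraction",
                                         fraction=self.split.fraction.resolve(vals)))
            else:
                events.append(SplitEvent(mode="free", child_sizes=tuple(
                    r.resolve(vals) for r in self.split.child_sizes)))
            for spec in self.post_epochs:
                events.append(self._epoch_from_spec(spec, vals))
        inbreeding = None
        if self.inbreeding is not None:
            inbreeding = tuple(r.resolve(vals) for r in self.inbreeding)
        return DemographicHistory(
            N_anc=self.n_anc.resolve(vals), events=events,
            inbreeding=inbreeding, pop_labels=self.pop_labels)

    @staticmethod
    def _epoch_from_spec(spec: EpochSpec, vals) -> Epoch:
        mig = None
        if spec.migration is not None:
            npop = len(spec.end_sizes)
            mig = tuple(tuple(
                0.0 if i == j else spec.migration[i][j].resolve(vals)
                for j in range(npop)) for i in range(npop))
        return Epoch(
            duration=spec.duration.resolve(vals),
            end_sizes=tuple(r.resolve(vals) for r in spec.end_sizes),
            dynamics=tuple(r.resolve(vals) for r in spec.dynamics),
            migration=mig,
            symmetric=spec.symmetric,
            migration_mask=spec.migration_mask,
        )

    # -- encode -----------------------------------------------------------
    def encode(self, history: DemographicHistory):
        """Inverse of :meth:`decode` for histories expressible in the template."""
        found = {}

        def record(ref, value):
            if isinstance(ref, V):
                if ref.name in found and not _close(found[ref.name], value):
                    raise ValueError(
                        f"inconsistent value for tied variable {ref.name}")
                found[ref.name] = value
            elif isinstance(ref, C):
                if not _close(ref.value, value):
                    raise ValueError(
                        f"history value {value!r} != template constant {ref.value!r}")

        record(self.n_anc, history.N_anc)
        epochs = [e for e in history.events if isinstance(e, Epoch)]
        split = history.split()
        pre = epochs[:len(self.pre_epochs)]
        post = epochs[len(self.pre_epochs):]
        if len(pre) != len(self.pre_epochs) or len(post) != len(self.post_epochs):
            raise ValueError("history epoch counts do not match the template")
        for spec, ep in zip(self.pre_epochs + self.post_epochs, pre + post):
            record(spec.duration, ep.duration)
            for r, s in zip(spec.end_sizes, ep.end_sizes):
                record(r, s)
            for r, d in zip(spec.dynamics, ep.dynamics):
                record(r, d)
            if spec.migration is not None:
                if ep.migration is None:
                    raise ValueError("template expects migration rates")
                npop = len(spec.end_sizes)
                for i in range(npop):
                    for j in range(npop):
                        if i != j:
                            record(spec.migration[i][j], ep.migration[i][j])
        if (self.split is None) != (split is None):
            raise ValueError("split presence does not match the template")
        if split is not None:
            if split.mode != self.split.mode:
                raise ValueError("split mode does not match the template")
            if split.mode == "fraction":
                record(self.split.fraction, split.fraction)
            else:
                for r, s in zip(self.split.child_sizes, split.child_sizes):
                    record(r, s)
        if self.inbreeding is not None:
            if history.inbreeding is None:
                raise ValueError("template expects inbreeding coefficients")
            for r, f in zip(self.inbreeding, history.inbreeding):
                record(r, f)
        values = []
        for var in self.space:
            if var.name not in found:
                raise ValueError(f"variable {var.name} not determined by the history")
            values.append(found[var.name])
        return values


def _close(a, b):
    if isinstance(a, str) or isinstance(b, str):
        return a == b
    return math.isclose(a, b, rel_tol=1e-12, abs_tol=0.0)


def decode(values, template: ModelTemplate) -> DemographicHistory:
    return template.decode(values)


def encode(history: DemographicHistory, template: ModelTemplate):
    return template.encode(history)


# ---------------------------------------------------------------------------
# structure-model construction


def build_space(structure, migration=True, symmetric=False,
                migration_masks=None, dynamics=DYNAMICS, split_mode="fraction",
                inbreeding=False, fixed=None, bounds=None,
                pop_labels=None) -> ModelTemplate:
    """Build the template for a structure model.

    Variable order is deterministic: ancestral size; then per pre-split epoch
    (oldest first) duration, end size, dynamic; then the split variable(s);
    then per post-split epoch duration, end sizes, dynamics and migration
    rates; inbreeding coefficients last.  Dynamic variables are omitted when
    the allowed subset is a singleton; masked migration pairs are omitted;
    symmetric migration collapses each pair to one rate.
    """
    if not isinstance(structure, ModelStructure):
        structure = ModelStructure(tuple(structure))
    dynamics = tuple(dynamics)
    if not dynamics or any(d not in DYNAMICS for d in dynamics):
        raise ValueError("allowed dynamics must be a non-empty subset of "
                         f"{DYNAMICS}")
    b = dict(DEFAULT_BOUNDS)
    b.update(bounds or {})
    two_pops = structure.n_pops == 2
    if migration_masks is not None and symmetric:
        m = migration_masks
        if bool(m[0][1]) != bool(m[1][0]):
            raise ValueError("migration mask inconsistent with symmetric flag")
    variables = []
    fixed = dict(fixed or {})

    def cont(name, kind):
        lo, hi = b[kind]
        # sizes and durations span many decades: sample and refine them on a
        # log scale (migration and fractions keep linear scales)
        variables.append(Variable(name, "continuous", lo, hi,
                                  log_scale=(kind in ("size", "duration")),
                                  fixed_value=fixed.pop(name, None)))
        return V(name)

    def dyn(name):
        if len(dynamics) == 1:
            return C(dynamics[0])
        variables.append(Variable(name, "categorical", categories=dynamics,
                                  fixed_value=fixed.pop(name, None)))
        return V(name)

    n_anc = cont("N_anc", "size")
    pre = []
    for k in range(2, structure.counts[0] + 1):
        duration = cont(f"dur_pre{k}", "duration")
        size = cont(f"N_pre{k}", "size")
        pre.append(EpochSpec(duration, [size], [dyn(f"dyn_pre{k}")]))

    split = None
    post = []
    if two_pops:
        if split_mode == "fraction":
            split = SplitSpec("fraction", fraction=cont("split_frac", "fraction"))
        elif split_mode == "free":
            split = SplitSpec("free", child_sizes=[
                cont("N_split_pop0", "size"), cont("N_split_pop1", "size")])
        else:
            raise ValueError("split mode must be 'fraction' or 'free'")
        if migration_masks is None:
            mask = ((False, True), (True, False)) if migration else \
                   ((False, False), (False, False))
        else:
            mask = tuple(tuple(bool(x) for x in row) for row in migration_masks)
            if not migration:
                mask = ((False, False), (False, False))
        for k in range(1, structure.counts[1] + 1):
            duration = cont(f"dur_post{k}", "duration")
            sizes = [cont(f"N_post{k}_pop0", "size"),
                     cont(f"N_post{k}_pop1", "size")]
            dyns = [dyn(f"dyn_post{k}_pop0"), dyn(f"dyn_post{k}_pop1")]
            mig = None
            if mask[0][1] or mask[1][0]:
                if symmetric:
                    m = cont(f"m_post{k}", "migration")
                    mig = [[C(0.0), m], [m, C(0.0)]]
                else:
                    m01 = cont(f"m_post{k}_01", "migration") if mask[0][1] else C(0.0)
                    m10 = cont(f"m_post{k}_10", "migration") if mask[1][0] else C(0.0)
                    mig = [[C(0.0), m01], [m10, C(0.0)]]
            post.append(EpochSpec(duration, sizes, dyns, migration=mig,
                                  symmetric=symmetric, migration_mask=mask))
    inb = None
    if inbreeding:
        n_final = 2 if two_pops else 1
        inb = [cont(f"F_pop{p}", "inbreeding") for p in range(n_final)]
    if fixed:
        raise ValueError(f"fixed parameters not in the space: {sorted(fixed)}")
    space = ParameterSpace(variables)
    return ModelTemplate(structure, space, n_anc, pre, split, post, inb,
                         pop_labels=pop_labels,
                         options=dict(migration=migration, symmetric=symmetric,
                                      migration_masks=migration_masks,
                                      dynamics=dynamics, split_mode=split_mode,
                                      inbreeding=inbreeding, bounds=bounds))


# ---------------------------------------------------------------------------
# structure increment


def increase_structure(template: ModelTemplate, values, component=None):
    """Split one epoch in two so the represented history is unchanged.

    The most recent epoch of the chosen component is divided into two halves
    of equal duration; the intermediate end sizes are taken from the size
    trajectory at the midpoint, and both halves inherit the dynamics and
    migration rates.  When the chosen component holds only the ancestral
    equilibrium epoch, a new constant epoch at the ancestral size is appended
    instead (also likelihood-neutral).  Returns ``(new_template, new_values)``.
    """
    counts = list(template.structure.counts)
    if component is None:
        component = 0
    if component >= len(counts):
        raise ValueError("no such structure component")
    counts[component] += 1
    opts = template.options
    if not opts:
        raise ValueError("structure increment requires a build_space template")
    new_template = build_space(ModelStructure(tuple(counts)),
                               pop_labels=template.pop_labels, **opts)
    vals = template.space.as_dict(values)
    history = template.decode(values)
    allowed = opts.get("dynamics", DYNAMICS)
    new_vals = dict(vals)

    s1_old = template.structure.counts[0]
    if component == 0:
        if s1_old == 1:
            # append a constant-at-N_anc epoch right after equilibrium
            lo, hi = dict(DEFAULT_BOUNDS, **(opts.get("bounds") or {}))["duration"]
            new_vals["dur_pre2"] = math.sqrt(lo * hi)
            new_vals["N_pre2"] = vals["N_anc"]
            if len(allowed) > 1:
                new_vals["dyn_pre2"] = CONSTANT if CONSTANT in allowed else allowed[0]
        else:
            # split the most recent pre epoch (template index s1_old - 2)
            k = s1_old            # epoch label being split
            ep_index = k - 2      # position within history.events
            ep = history.events[ep_index]
            start = history.start_sizes_of(ep_index)
            mid = size_trajectory(ep, start, ep.duration / 2.0)
            # shift labels: epochs after k keep their contents, renumbered +1
            for kk in range(s1_old, k, -1):
                pass  # k is the last pre epoch; nothing to renumber
            new_vals[f"dur_pre{k}"] = ep.duration / 2.0
            new_vals[f"N_pre{k}"] = mid[0]
            new_vals[f"dur_pre{k + 1}"] = ep.duration / 2.0
            new_vals[f"N_pre{k + 1}"] = ep.end_sizes[0]
            if len(allowed) > 1:
                new_vals[f"dyn_pre{k}"] = ep.dynamics[0]
                new_vals[f"dyn_pre{k + 1}"] = ep.dynamics[0]
    else:
        s2_old = template.structure.counts[1]
        k = s2_old
        ep_index = (s1_old - 1) + 1 + (k - 1)   # pre epochs, split, post epochs
        ep = history.events[ep_index]
        start = history.start_sizes_of(ep_index)
        mid = size_trajectory(ep, start, ep.duration / 2.0)
        new_vals[f"dur_post{k}"] = ep.duration / 2.0
        new_vals[f"dur_post{k + 1}"] = ep.duration / 2.0
        for p in range(2):
            new_vals[f"N_post{k}_pop{p}"] = mid[p]
            new_vals[f"N_post{k + 1}_pop{p}"] = ep.end_sizes[p]
            if len(allowed) > 1:
                new_vals[f"dyn_post{k}_pop{p}"] = ep.dynamics[p]
                new_vals[f"dyn_post{k + 1}_pop{p}"] = ep.dynamics[p]
        for name in (f"m_post{k}", f"m_post{k}_01", f"m_post{k}_10"):
            if name in vals:
                new_vals[name.replace(f"post{k}", f"post{k + 1}")] = vals[name]

    out = []
    for var in new_template.space:
        if var.name not in new_vals:
            raise RuntimeError(f"increment left variable {var.name} unset")
        x = new_vals[var.name]
        if var.kind == "continuous":
            x = var.clip(float(x))
        out.append(x)
    return new_template, out
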