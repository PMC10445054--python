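# Methods

`demfit` fits one- and two-population demographic histories to allele
frequency spectra (AFS) by maximizing a Poisson random-field composite
likelihood with a genetic algorithm over mixed continuous/discrete model
parameterizations. This note records the model, the numerics, the defaults
and their rationale, and the limits of what the packaged tests demonstrate.

## Demographic model

A history starts from an ancestral population of diploid size `N_anc` at
neutral mutation–drift equilibrium and proceeds through an ordered sequence
of epochs and at most one population split. Each epoch has a duration (in
generations), per-population end sizes, a per-population size dynamic —
constant, linear or exponential interpolation from the epoch's start sizes —
and, after a split, a matrix of continuous migration rates. `m[dest][source]`
is the fraction of the receiving population replaced by migrants per
generation; masks can disable individual rates and a symmetry flag collapses
each pair to one rate. Epochs store *end* sizes; start sizes are the previous
event's end sizes, except under the constant dynamic, where an instantaneous
jump at the epoch start is permitted. This one scheme expresses both
instantaneous expansions and smooth growth. Splits either divide the parent
size by a fraction `s` (children sum exactly to the parent size) or assign
two free child sizes.

A *model structure* `(s1, s2)` counts epochs before and after the split. The
first epoch is the ancestral equilibrium and contributes only `N_anc`; every
later epoch contributes a duration, end sizes, and (when more than one
dynamic is allowed) a categorical dynamic variable. Default bounds, in
physical units: sizes on [1e2, 1e8] diploids, durations on [1, 1e7]
generations, migration on [0, 1e-2] per generation, split fraction on
[1e-3, 1−1e-3], inbreeding coefficients on [0, 1]. All are overridable; the
defaults span every packaged ground-truth value. Sizes and durations are
log-scaled variables — sampled log-uniformly and refined in log10
coordinates — because their boxes span 6–7 decades and every decade is a
priori equally plausible; migration and fractions stay linear (their boxes
include 0 or span less than a decade).

Inbreeding is modelled at sampling time, constant over the history: with
coefficient `F`, the number of inbred individuals among `n` sampled diploids
is Binomial(n, F); an inbred individual contributes one sampled allele
counted twice, so the diploid derived-allele count is a hypergeometric
redistribution of a smaller haploid draw. `F = 0` reduces exactly to
ordinary diploid sampling and `F = 1` empties every odd count bin; both
identities are tested exactly.

Selection and dominance fields exist on the history type but the built-in
engine refuses them: they are declared for interface completeness only.

## Expected-spectrum engine

The engine evolves the sampled spectrum directly. Writing `Phi_i` (or
`Phi_ij`) for the expected count of sites at derived-allele count `i`, the
Wright–Fisher diffusion integrated against Bernstein polynomials yields a
linear ODE on the `(n+1)`- or `(n1+1)(n2+1)`-dimensional bin array:

* Neutral drift is tridiagonal per axis and — a classical fact — closes
  exactly at the sample size, so single-population spectra are exact up to
  time integration error.
* The migration advection term needs the spectrum at one extra sample on
  the donor axis; it is closed with a quadratic-moment jackknife: a local
  quadratic frequency density is fitted through three consecutive bins by
  matching their beta-weight moments and integrated against the
  size-`(n+1)` weights.
* New mutations inject `n·theta0/2` into the singleton bins per unit time
  (time in `2·N_anc` generations, `theta0 = 4·N_anc·mu·L`), making the
  result exactly linear in `theta0`; internally everything is computed per
  unit `theta0`.
* At a split the spectrum redistributes hypergeometrically over the two
  descendant sample sizes; the pre-split phase is computed at their sum.

The two monomorphic corner bins are pinned to zero throughout. Their
diffusion-limit expectations are divergent truncation artifacts, they are
masked in every likelihood, and letting them accumulate absorbed mass would
pollute the jackknife stencils of the edge rows — pinning them restores the
structure-increment invariance below to machine precision. The residual
closure bias this leaves in corner-adjacent bins is diluted by
`corner_padding`: two-population spectra are computed at `n + 4` samples per
axis by default and projected down (projection is exact for expectations).
With the default padding the engine matches a Monte-Carlo structured
coalescent estimate of the orangutan-style isolation-with-migration
spectrum (5+5 haploids, 1e5 replicates) within three standard errors in
every unmasked bin, across independent oracle realizations; at 4e5
replicates the residual per-bin bias is below the ~0.5% noise floor.

Time integration per epoch:

* Constant coefficients (all dynamics constant, sizes and rates fixed):
  exact propagation by a matrix exponential of the augmented (generator +
  source) matrix.
* Time-varying coefficients, `method="adaptive"` (default): implicit Radau
  integration with the analytic Jacobian, to `rtol`/`atol` (defaults 1e-8 /
  1e-12). A per-epoch cap on right-hand-side evaluations (`max_rhs_calls`,
  default 30,000) turns pathological integrations into reported failures.
* `method="fixed_step"`: a midpoint-exponential rule — coefficients are
  frozen at each substep midpoint and propagated exactly — with the substep
  count proportional to the total log-variation of the coefficients (6–48
  steps). Second-order accurate (~1e-3 relative on the orangutan truth),
  immune to stiffness, and with bounded cost per candidate; used for bulk
  search evaluations.

Validity domain: the jackknife closure is not trustworthy for
population-scaled migration `2·N_ref·m` above ~500; such candidates, and
integrations exceeding their budget, raise errors that the search maps to
`-inf` fitness. This matters only for search-space corners (e.g. a 1e8
ancestral size with 1e-2 migration); all realistic rates lie far inside the
domain.

Theta handling has two modes: `fixed_theta0` (the default; `mu·L` known) and
`optimal_scaling`, which rescales a per-unit-theta spectrum by the analytic
Poisson maximum-likelihood factor `sum(data)/sum(model)`.

## Likelihood

The composite log-likelihood sums `d·ln m − m − ln Γ(d+1)` over unmasked
bins; monomorphic corners are always masked, folded spectra mask the
majority bins, and projected (hence non-integer) data use the log-gamma
continuation. A model bin of zero mass under positive data yields `-inf`.
Folding sums complementary derived-count bins, with self-complementary bins
averaged rather than doubled.

## Genetic algorithm

Ten hyperparameters: generation size, initial-design constant, four
composition fractions (elites, mutants, crossover offspring, fresh
randoms), and the mutation strength/rate with their adaptation constants.
Two presets are packaged: the original default and the tuned configuration
found by hyperparameter optimization (generation size 10, initial-design
constant 10, fractions 0.30/0.20/0.30/0.20, mutation strength 0.776 with
constant 1.302, mutation rate 0.273 with constant 1.475). Design choices the
published description leaves open, decided here:

* Initial design = `gen_size × n_init_const` uniform (log-uniform for
  log-scaled variables) samples, all evaluated, best `gen_size` retained.
* Mutation: each free variable mutates with probability
  `mutation_strength` (at least one always mutates); continuous values are
  perturbed multiplicatively by `1 ± δ` with half-normal `δ` of scale
  `mutation_rate` and clipped to bounds; categorical values resample
  uniformly among the other categories.
* Crossover: uniform per-variable inheritance, constrained to take at
  least one variable from each parent when the parents differ.
* Parent selection is fitness-rank weighted (weights n, n−1, …, 1).
* Adaptation follows the one-fifth success rule, generation-wise: on
  improvement multiply by the constant, otherwise divide by its fourth
  root; both parameters clip to (1e-4, 1].
* Composition counts come from largest-remainder apportionment, so they
  sum to the generation size for any fraction vector.
* Ties in fitness rank by creation order (stable sort); `-inf` candidates
  are legal and rank last.

The stop criterion is `1000 / gen_size` consecutive generations without
improvement of the best fitness (100 for generation size 10, 20 for 50); an
optional evaluation budget terminates earlier and is never exceeded.
Identical candidate vectors are served from a cache and not recounted.

## Inference pipeline

`DemographicModel.fit` runs independent seeded GA searches (each with its
own evaluation budget) on the fixed-step engine, re-scores the best
candidate with the adaptive reporting settings, and polishes it with
Nelder–Mead over the continuous variables in unit-box coordinates (log10
scale for log-scaled variables), so parameters whose physical magnitudes
differ by nine orders contribute comparable simplex steps. The polish has
two phases — a pass on the bounded fixed-step surface that closes most of
the distance cheaply, then a pass on the adaptive reporting surface, where
integration is fast near the optimum; categoricals stay frozen and the
reported fitness never decreases. The reported history is translated
between physical and genetic units by `N_anc` (sizes), `2·N_anc`
generations (times) and `2·N_anc` (migration); reports carry both systems.

`fit_ladder` climbs a structure ladder: one GA stage per increment of the
leftmost structure component still below its final count. The incremented
epoch is the most recent one of that component, divided into two halves of
equal duration with intermediate sizes taken from the size trajectory at
the midpoint, so the represented history — and therefore the incumbent's
likelihood — is unchanged (verified to 1e-8 relative under the adaptive
integrator; the equilibrium-only component instead gains a constant epoch
at `N_anc`, equally likelihood-neutral). Transformed incumbents fill the
elite share of the next stage's first generation; the remainder is fresh
random.

Model comparison utilities implement the published protocol: the plain
(not Godambe-adjusted — flagged in the output) likelihood-ratio test for
nested models; better/worse/incomparable classification by strict
comparison of the median and both quartiles (linear-interpolation
quantiles) of repeated-run likelihoods; speedup
`1 − mean(evals_new)/mean(evals_default)`; and the `ceil(Y/X)` restart
budget for matching a cheaper optimizer's computational cost.

## Synthetic truths and oracles

Two packaged ground-truth histories drive the recovery experiments: the
fruit-fly African/European isolation history (ancestral 1,720,600; African
expansion to 8,603,000 at 600,000 generations ago; split 158,000
generations ago; European bottleneck 2,200 then 1,075,000 from 154,600
generations ago; mu 5.49e-9, L 1.1e8) and the orangutan
isolation-with-migration history (ancestral 17,934 splitting into 10,617
and 7,317 — summing exactly to the ancestral size — 20,157 generations
ago, changing exponentially to 8,805 and 37,661 under asymmetric migration
0.66e-5 and 1.10e-5 per generation; mu 1.5e-8, L 2.87e9). Recombination
rates are stored as inert metadata: the AFS carries no linkage
information. Default sample sizes are 10 haploids (5 diploid individuals)
per population, mirroring the simulated datasets these truths come from.

The recovery experiment (`fixtures.refit_noise_free`, also the acceptance
script) generates each fixture's noise-free expected spectrum with the same
reporting settings used for the final likelihoods, so the likelihood
optimum sits exactly at the stored truth and recovery error measures the
optimizer, not the engine. Four seeded GA runs (evaluation budget 200 per
free parameter, following the published budget rule) plus the two-phase
polish recover every parameter of both fixtures — sizes, times and
migration rates — to well under 1% on noise-free data. The fruit-fly
bottleneck pair (size 2,200 for 3,400 generations) sits on a likelihood
ridge (the spectrum mainly constrains the drift the bottleneck causes), so
its two members converge last and would be the first to degrade under
sampling noise; the fixture's identifiability note records this.

Two engine-independent oracles gate correctness:

* A closed-form single-population piecewise-constant SFS: expected
  coalescent waiting times from the pure-death lineage chain (augmented
  matrix exponentials per epoch, analytic infinite tail), combined with
  the exchangeable family-size weights. No code shared with the engine.
* A Monte-Carlo structured-coalescent estimate of expected branch lengths
  subtending each joint count class, computed with msprime/tskit
  (branch-mode AFS over independent non-recombining genealogies), with
  per-bin standard errors. Linear size trajectories are approximated by a
  64-piece constant staircase there; constant and exponential dynamics are
  exact.

The Poisson sampler (`sample_afs_poisson`) draws independent Poisson counts
per unmasked bin — exactly the observation model under which the composite
likelihood would be a true likelihood.

What the synthetic data do **not** emulate: linkage between sites (real
spectra are correlated across bins, which the composite likelihood already
ignores), ancestral-state misidentification, genotyping error and missing
data beyond the VCF projection path, and more than two populations. Passing
recovery tests therefore demonstrates optimizer and engine correctness
under the model's own assumptions, not robustness to their violation.

## File formats

The `.fs` dialect: a header line with the shape integers, a
`folded`/`unfolded` token and optional quoted population labels; a
row-major data line written with 17 significant digits (round-trips
doubles exactly); a row-major 0/1 mask line (1 = masked), defaulting to
the corner mask when absent. VCF input parses GT fields only (phasing
irrelevant for counts), keeps biallelic SNPs, honours an `AA` INFO field
for ancestral alleles (unfolded output without it is an error), and either
skips incompletely called sites or, when target sample sizes are given,
projects each site's called alleles down hypergeometrically. Histories are
exported as demes-specification YAML (time in generations, oldest events
at the largest times); the test suite validates every written document
with the independent demes parser. Reports are JSON with a stable key
order, parameters in both unit systems, the log-likelihood, theta,
evaluation counts and seeds.

## Known limitations

* Two populations at most; one split; no pulse admixture, no linkage
  statistics, no selection or dominance in the likelihood.
* The migration closure's validity bound (scaled migration ≲ 500) is
  enforced, not padded around; candidates beyond it are search failures.
* Confidence intervals are out of scope; the likelihood-ratio test is
  unadjusted for the composite nature of the likelihood and is flagged as
  such.
* The fixed-step search propagator trades ~1e-3 relative spectrum accuracy
  for bounded cost; final reported likelihoods and the polish stage always
  use the adaptive integrator.
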