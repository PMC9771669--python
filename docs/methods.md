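# Methods

## Model and assumptions

Individual growth is Von Bertalanffy with an environmentally scaled
asymptote: d&ell;/dt = r_B (f_t ℓ∞ − &ell;), with f_t the dimensionless
limitation of assimilation (food, temperature, ...) and ℓ∞ the species
maximum asymptotic length.  Treating f_t as Gaussian with time-varying
mean and variance makes individual length a mean-reverting diffusion,

    dl = r_B (μ_t ℓ∞ − l) dt + r_B σ_t ℓ∞ dW_t ,

and a cohort's length distribution stays Gaussian forever.  Assumptions
the package inherits from this construction:

* one observation per individual; samples are (or are weighted to be)
  random with respect to length within each (occasion, age) cell;
* surveys are evenly spaced and all members of a cohort are born in the
  same inter-survey interval (ages are integer classes);
* only the asymptote responds to the environment — r_B is shared by all
  individuals and years (the two are strongly confounded in single-
  observation data, and energetics places the environment in the
  asymptote);
* the limitation over one interval is summarized by its average mean and
  variance (μ̄_T, σ̄²_T); within-interval dynamics are not resolved;
* within-cohort length distributions are Gaussian, so a cohort mean above
  the current asymptote shrinks.  An opt-in non-shrink variant replaces
  the mean update by max(previous mean, update); fit without it first and
  check whether large declines actually occur, because it inflates the
  influence of young cohorts.

Discretizing over one interval gives the recursions in the README.  The
time step is fixed at one sampling interval and all rates are per
interval; non-uniform survey spacing is out of scope.

### The variance product

The per-interval variance parameter `sigma2_linf2` is *defined* as the
quantity entering the variance recursion

    V' = V e^(−2 r_B) + sigma2_linf2 (1 − e^(−2 r_B)) / (2 r_B) ,

with stationary value `sigma2_linf2 / (2 r_B)`.  Relative to the diffusion
coefficient of the stochastic equation above, the Ito isometry gives
`sigma2_linf2 = (r_B σ_t ℓ∞)²`; the synthetic module applies exactly this
mapping, which makes the recursion the exact law of the simulated process
(verified against 10⁵-path Euler–Maruyama ensembles).  Units: mm² × time.
When a species ℓ∞ is supplied for reporting, estimates are rescaled as
μ̄ = mu_linf/ℓ∞ and σ̄² = sigma2_linf2/ℓ∞².

## Parameters, defaults, units

| parameter | meaning | unit | default / start |
|---|---|---|---|
| r_B | growth-rate scalar | 1/interval | started from a pooled VB curve fit |
| E, V at first age | boundary distribution per occasion | mm, mm² | pooled-curve intercept; weighted variance of youngest class |
| E, V at first occasion | boundary distribution per older age | mm, mm² | pooled curve; variance interpolated along the recursion between youngest- and oldest-class variance |
| mu_linf | mean asymptotic length per interval (× group) | mm | pooled-curve asymptote |
| sigma2_linf2 | variance product per interval (× group) | mm²·time | 2 r_B × weighted variance of the oldest class (so the stationary variance matches it) |
| variance floor | guards degenerate cells | mm² | 1e-8 (far below the ≥5 mm measurement resolution); floored cells are counted in the fit statistics |

Free-parameter count: k = 1 + 2 n_T + 2 (n_a − 1) + 2 n_intervals n_groups,
with n_intervals = 1 for the constant-environment variant, n_T − 1
otherwise; AIC = 2k + 2 NLL on the weighted likelihood.  Weights enter as
multiplicities, so rescaling all weights rescales the NLL but not the
optimum.  Cells with zero weight contribute nothing; their boundary
parameters stay in the vector (weakly identified) and are reported.

## Optimization

Fitting runs in log-parameter space (all parameters are positive, and the
transform equalizes scales), with a derivative-free local optimizer
first — Powell by default, Nelder–Mead as an option, relative tolerance
1e-10, evaluation cap 1500 per dimension — followed by an L-BFGS-B polish
using the exact reverse-mode gradient of the likelihood through the
recursions (unit-tested against central differences).  The polish exists
because derivative-free methods demonstrably stall in the weakly
identified, curved valleys that appear when occasions carry little or no
data; it changes well-identified fits by ~nothing and costs a few hundred
evaluations.  Likelihood evaluation uses per-cell sufficient statistics
(Σw, Σwx, Σwx²), so its cost is independent of the number of fish.
Optional seed-jittered restarts are available (off by default; a single
start suffices on every packaged scenario).

Group-structured environments classify a cohort by its *age* or its
*predicted mean length* at the start of each interval (start-of-interval
state is used for causality; classes are lower-closed/upper-open, and the
group count multiplies only the environment parameters).  With one
all-encompassing group the fit coincides with the ungrouped model.

## Synthetic data

`generate_dataset` presets define the study conditions: annual survey,
grid of 15 occasions × 8 age classes (first age 1), r_B = 0.3/yr,
ℓ∞ = 780 mm, Gaussian birth length 50 ± 10 mm, limitation noise
σ_t = 0.13 (stationary within-cohort sd ≈ 40 mm), and 300 weighted fish
per cell sampled from 3000-individual cohorts.  Scenarios vary the mean
limitation: constant (0.7), sinusoidal in [0.5, 0.9] (period 10 yr),
year-to-year independent, distinct by age group (split at age 4), a
length-biased survey, and a "plaice-like" regime at published estimates
for North Sea plaice (r_B = 0.2977/yr, σ̄² = 0.0268 yr, i.e. stationary sd
≈ 165 mm) used for the jackknife experiment, whose claims concern exactly
that high-variation regime.

Two simulators exist on purpose: an Euler–Maruyama integrator (the
independent Monte-Carlo oracle; paths may transiently exceed the
asymptote or shrink — the Gaussian model permits it, and no boundary is
imposed) and an exact per-interval Ornstein–Uhlenbeck transition sampler
used to build large datasets without discretization error.  One seed
governs births, growth increments and survey draws in a documented order.

The survey sampler draws fish with probability proportional to a
catchability function of length.  The biased-survey preset uses
exponential selectivity (constant log-slope, e-folding 250 mm) and pools
each occasion into a single draw: pooled sampling is both how selective
gear operates and the condition under which inverse catch-rate-per-length
weights (the CPUE analogue, computed on 5 mm bins per occasion,
normalized to mean 1) are an exact inverse-probability correction.  Note
that the *direction* of the limitation bias under selectivity follows the
age-gradient of the cell-mean bias, not its sign: selectivity whose
log-slope decays with length (e.g. a saturating logistic) can bias the
limitation downward even though every cell mean is biased upward.

What the generator does not emulate: spatial structure, mortality or
year effects in selectivity, ageing error, overdispersed or non-Gaussian
cell distributions, and unequal survey intervals.  Passing tests
therefore demonstrate correctness of the estimator under its own
assumptions, not robustness to these violations.

## Jackknife

`jackknife_years` refits with one occasion's rows removed, keeping the
grid so parameter indexing stays aligned; replicate fits use identical
optimizer settings, and starting values are recomputed from the reduced
data (the default, matching how the analysis is run in practice).  An
omitted year leaves the omitted occasion's boundary parameters free and
the adjacent intervals' mean asymptotic lengths identified essentially
only through the combination μ̄_{t−1} e^(−r_B) + μ̄_t, so cold-started
refits over- and under-shoot in those two intervals in an anticorrelated
pair — the characteristic signature of a missing year, bounded well below
the within-cohort spread in the plaice-like regime.  The alternative
`refit_start="full-fit"` warm-starts replicates from the full-data
optimum and measures the pure maximum-likelihood influence of the omitted
year instead, which is far smaller (sub-mm at desk scale) and spread over
all intervals; choose it when the question is statistical influence
rather than robustness of the fitting procedure.

## Numerical choices and degenerate inputs

* Variances are propagated un-clamped (non-negativity is analytic);
  likelihood evaluation floors cell variances at 1e-8 mm² and flags it.
* Observation tables validate row-wise (integer time/age, positive
  length, finite non-negative weight, on-lattice cell) and keep rejects
  with reasons rather than failing wholesale; an all-rejected file errors.
* Starting values fall back to a flat growth curve when the pooled VB
  curve fit is degenerate (e.g. constant lengths), with a warning.
* Model-comparison requires all fits to share the observation table
  (checked by a data fingerprint); the constant-environment variant is
  treated as nested in the per-interval one for likelihood-ratio tests.
* Serialized outputs use 12 significant digits, which round-trips
  predictions to better than 1e-10 relative.
* Problem sizes in the test-suite experiments (e.g. 10⁵ simulation paths,
  15 × 8 × 300 surveys, single-omission jackknife) are the package's
  reference desk-scale designs; estimates at these sizes are accurate to
  well under the tolerances asserted.

## Known limitations

ℓ∞ and the limitation are only jointly identified (products are fitted;
scaled reporting requires an external ℓ∞).  r_B is assumed time- and
age-invariant.  No standard errors are reported for the fitted
parameters; model comparison relies on AIC and likelihood-ratio tests.
Group boundaries are user-supplied, and a grouped fit with too many
classes dilutes the per-class data; comparing the grouped variance
estimates against the ungrouped fit (lower within a group ⇒ the grouping
captures real segregation) is the intended diagnostic.  The log-normal
error-structure alternative (which would forbid shrinkage exactly) is not
implemented.
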