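# vbcohort

Cohort-level Von Bertalanffy growth curves from length-at-age data in
which **every individual is measured only once** — the most common kind of
survey data for fish and other aged animals (ages from otoliths or other
hard structures, lengths from routine monitoring).

The package estimates, simultaneously:

* the Von Bertalanffy growth-rate scalar *r*<sub>B</sub>,
* the length distribution of every cohort at every sampling occasion,
* and the **environmental limitation of growth** — its mean and its
  between-individual variance — separately for every inter-survey
  interval (and, optionally, for a priori age or length groups).

It is aimed at fisheries and ecological researchers who want a proxy for
time-varying food limitation or density dependence, and at stock-assessment
users who need length-at-age distributions per cohort rather than one
static growth curve.

## The model

Individual growth follows the Von Bertalanffy equation
d&ell;/d*t* = *r*<sub>B</sub>(*f*<sub>t</sub>&ell;<sub>∞</sub> − &ell;),
where the asymptotic length is the species maximum &ell;<sub>∞</sub> scaled
by an environmental limitation *f*<sub>t</sub> ∈ (0, 1].  Treating
*f*<sub>t</sub> as Gaussian white variation with per-interval mean
μ̄<sub>T</sub> and variance σ̄²<sub>T</sub> turns individual growth into a
mean-reverting stochastic process, and the length of a **cohort** (all fish
born in the same inter-survey interval) stays Gaussian with moments that
obey one-step recursions across the discrete time × age lattice:

```
E[l(T+1, a+1)] = E[l(T, a)] e^(−r_B) + μ̄_T ℓ∞ (1 − e^(−r_B))
V[l(T+1, a+1)] = V[l(T, a)] e^(−2 r_B) + σ̄²_T ℓ∞² (1 − e^(−2 r_B)) / (2 r_B)
```

with stationary within-cohort variance σ̄²<sub>T</sub>ℓ∞² / (2 *r*<sub>B</sub>).
Free parameters are *r*<sub>B</sub>, the length distribution at the
youngest age for every occasion, the distribution of each older age class
at the first occasion, and the per-interval products μ̄<sub>T</sub>ℓ∞ and
σ̄²<sub>T</sub>ℓ∞² (only the products are identifiable; supplying a species
&ell;<sub>∞</sub> rescales them into a dimensionless limitation).  Fitting
maximizes a weighted Gaussian likelihood over all observed cells — weights
such as inverse CPUE (catch per unit effort) per length class correct
length-biased catchability — with a derivative-free optimizer in
log-parameter space followed by an exact-gradient quasi-Newton polish.

## Worked example

`examples/recover_known_parameters.py` simulates the reference survey
design (15 years × 8 age classes, sinusoidal limitation between 0.5 and
0.9 of &ell;<sub>∞</sub> = 780 mm, 300 weighted fish per cell) and refits it:

```
true r_B = 0.3000, estimated r_B = 0.2969 (1.03% off)
correlation(true, fitted) of the limitation trajectory: 0.9997

interval   true mu_linf   fitted mu_linf
[ 0, 1)        546.0           555.0
[ 1, 2)        637.7           642.4
[ 2, 3)        694.4           698.4
...
```

The fitted per-year mean asymptotic lengths (mm) track the generating
sinusoid and the growth-rate scalar is recovered to ~1%.  The other
examples each demonstrate one capability: `fit_growth_curves.py`
(constant- vs varying-environment fits, AIC and likelihood-ratio
comparison), `cpue_weighting.py` (length-biased sampling corrected by
inverse-catch-rate weights: bias +4.3 mm → +0.7 mm), `jackknife_sensitivity.py`
(omitting one survey year perturbs only the adjacent intervals, by ≪ the
within-cohort spread) and `simulate_and_check_moments.py` (the recursions
agree with a 50,000-path simulation of the underlying stochastic process).

A thin command line mirrors the library for shell use:

```bash
vbcohort simulate --scenario trending-env --seed 1 --out sim/
vbcohort fit sim/observations.csv --env varying --linf 780 --out fit/
vbcohort jackknife sim/observations.csv --out jk/
vbcohort compare sim/observations.csv --variants constant,varying --out cmp/
vbcohort predict fit/params.json --out pred/
```

Input is delimited text (comma or tab) with columns `time`, `age`,
`length` (mm, `length_mm` accepted) and optional `weight`.

## Layout

```
src/vbcohort/      growth.py      mean/variance recursions, grid prediction
                   likelihood.py  observation tables, weighted Gaussian NLL, LRT
                   fit.py         parameterization, starting values, optimizers
                   synthetic.py   SDE simulator, survey sampler, scenario presets
                   diagnostics.py jackknife, model comparison
                   io.py, cli.py  file formats and the command line
examples/          one short script per capability
tests/             unit, property and end-to-end scientific tests
docs/methods.md    modelling assumptions, numerics, design choices
```
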