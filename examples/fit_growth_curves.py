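"""Fit constant- and time-varying-limitation growth models to a survey.

Builds a small synthetic survey (6 years x 4 age classes) whose true
environmental limitation oscillates between years, fits both model
variants, and compares them by AIC and a likelihood-ratio test.  The
varying-environment model should win decisively because the generating
limitation really does change from year to year.
"""

import warnings

import vbcohort as vb

warnings.simplefilter("ignore", RuntimeWarning)

grid = vb.GridSpec(t_min=0, n_t=6, a_min=1, n_a=4)
ds = vb.generate_dataset("trending-env", seed=11, grid=grid, n_per_cell=80)

constant = vb.fit_model(ds.observations, ds.grid, env="constant", l_inf=780.0)
varying = vb.fit_model(ds.observations, ds.grid, env="varying", l_inf=780.0)

print(f"observations: {len(ds.observations)} fish, grid {grid.n_t} years x {grid.n_a} ages")
print(f"constant environment: r_B={constant.params.r_b:.4f}  k={constant.stats.k}  "
      f"AIC={constant.stats.aic:.1f}")
print(f"varying  environment: r_B={varying.params.r_b:.4f}  k={varying.stats.k}  "
      f"AIC={varying.stats.aic:.1f}")
print()
print(vb.compare_models([constant, varying]).to_string(index=False))
print()
print("Per-interval estimates (mu_scaled = dimensionless limitation, given l_inf=780):")
print(varying.env_table().head(5).to_string(index=False))
print()
print("A lower AIC for the varying variant means year-to-year changes in the")
print("asymptotic length are supported by the data, not just within-cohort noise.")
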