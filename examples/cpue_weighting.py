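"""Correcting length-biased sampling with inverse-CPUE weights.

Simulates a survey whose gear catches large fish preferentially
(exponential length selectivity).  Fitting without weights overestimates
the mean asymptotic length; weighting every fish by the inverse of the
empirical catch rate of its 5 mm length bin removes most of the bias.
"""

import warnings

import vbcohort as vb

warnings.simplefilter("ignore", RuntimeWarning)

ds = vb.generate_dataset("biased-survey", seed=7)
true_mu = ds.truth.mu_linf[0, 0]

weighted = vb.fit_model(ds.observations, ds.grid, env="constant")
unweighted = vb.fit_model(ds.observations.unweighted(), ds.grid, env="constant")

bias_u = unweighted.params.mu_linf[0, 0] - true_mu
bias_w = weighted.params.mu_linf[0, 0] - true_mu
print(f"true mean asymptotic length: {true_mu:.1f} mm")
print(f"unweighted fit:  {unweighted.params.mu_linf[0, 0]:.1f} mm  (bias {bias_u:+.2f} mm)")
print(f"CPUE-weighted:   {weighted.params.mu_linf[0, 0]:.1f} mm  (bias {bias_w:+.2f} mm)")
print(f"bias removed: {100 * (1 - abs(bias_w) / abs(bias_u)):.0f}%")
print()
print("Catchability increasing with length inflates every cell mean, most at")
print("older ages where spread is largest, so the limitation is overestimated;")
print("inverse-catch-rate weights restore the population length distribution.")
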