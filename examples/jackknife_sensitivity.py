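"""How much does one missing survey year move the estimates?

Refits the varying-environment model with the middle survey year omitted
(conditions mimicking North Sea plaice: large within-cohort spread).  The
estimated mean asymptotic length shifts almost exclusively in the two
intervals adjacent to the omitted year — one overestimated, the other
underestimated — and by far less than the within-cohort spread.
"""

import warnings

import numpy as np

import vbcohort as vb

warnings.simplefilter("ignore", RuntimeWarning)

ds = vb.generate_dataset("plaice-like", seed=3)
omit = 7
summary = vb.jackknife_years(ds.observations, ds.grid, occasions=[omit], env="varying")

res = summary.results[0]
full = summary.full_fit
v_inf = vb.asymptotic_variance(full.params.r_b, float(full.params.sigma2_linf2.mean()))

print(f"omitted year: {omit};  2 x within-cohort sd = {2 * np.sqrt(v_inf):.0f} mm")
print("interval   delta mu_linf (mm)")
for t, d in zip(ds.grid.times[:-1], res.delta_mu_linf[:, 0]):
    marker = "  <- adjacent" if t in (omit - 1, omit) else ""
    print(f"[{t:2d},{t + 1:2d})   {d:+10.2f}{marker}")
print()
print("Intervals next to the missing year trade off against each other (only")
print("their combination stays well identified), but the perturbation is small")
print("relative to the variation between individual fish.")
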