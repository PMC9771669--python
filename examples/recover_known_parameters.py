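"""Parameter recovery on the standard synthetic survey design.

Generates the package's reference scenario (15 years x 8 ages, sinusoidal
limitation between 0.5 and 0.9 of the species maximum, 300 weighted fish
per cell), fits the varying-environment model and compares the estimates
with the generating truth.
"""

import warnings

import numpy as np

import vbcohort as vb

warnings.simplefilter("ignore", RuntimeWarning)

ds = vb.generate_dataset("trending-env", seed=101)
fit = vb.fit_model(ds.observations, ds.grid, env="varying", l_inf=780.0)

corr = np.corrcoef(ds.truth.mu_linf[:, 0], fit.params.mu_linf[:, 0])[0, 1]
print(f"true r_B = {ds.truth.r_b:.4f}, estimated r_B = {fit.params.r_b:.4f} "
      f"({100 * abs(fit.params.r_b - ds.truth.r_b) / ds.truth.r_b:.2f}% off)")
print(f"correlation(true, fitted) of the limitation trajectory: {corr:.4f}")
print()
print("interval   true mu_linf   fitted mu_linf")
for t, (mt, mf) in enumerate(zip(ds.truth.mu_linf[:, 0], fit.params.mu_linf[:, 0])):
    print(f"[{t:2d},{t + 1:2d})   {mt:10.1f}    {mf:12.1f}")
print()
print("The fitted per-year mean asymptotic lengths (mm) track the generating")
print("sinusoid; the growth-rate scalar is recovered to within a few percent.")
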