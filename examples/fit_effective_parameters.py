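"""Fit effective Gompertz parameters to a noisy synthetic untreated arm.

Generates one trajectory at the untreated antibody-study scale
(a=0.049, k=0.011 day^-1, N0=100, 5% multiplicative measurement noise,
observations every 2 days over days 0-40) and recovers the parameters by
nonlinear least squares on log size.
"""

import numpy as np

from tumorgl import GompertzParams, fit_gompertz
from tumorgl.synthetic import NoiseModel, generate_trajectory

truth = GompertzParams(a=0.049, k=0.011, N0=100.0)
days = np.arange(0.0, 41.0, 2.0)
traj = generate_trajectory(truth, None, days, NoiseModel(sd=0.05, seed=1),
                           subject_id="m1", arm="untreated")

res = fit_gompertz(traj)
p = res.params
print(f"a_eff = {p.a_eff:.4f} +/- {res.a_err:.4f} day^-1   (generating value 0.049)")
print(f"k_eff = {p.k_eff:.4f} +/- {res.k_err:.4f} day^-1   (generating value 0.011)")
print(f"effective carrying capacity = {p.effective_carrying_capacity:.0f} "
      f"(true {truth.carrying_capacity:.0f})")
print(f"correlation = {res.correlation_coefficient:.3f}, "
      f"RMS relative error = {res.rms_relative_error:.3f}")
print("Estimates land within the noise-determined uncertainty of the generating")
print("values; the errors are chi^2/dof-scaled standard errors of the fit.")
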