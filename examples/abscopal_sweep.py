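"""Abscopal effect: metastasis response for increasing RT-immune coupling.

The unirradiated metastasis receives no dose.  Each fraction delivered
to the primary (3 x 8 Gy, days 9-11) triggers, after a 2-day delay, an
immune kill-rate pulse of amplitude Y0 decaying with a 2-day time
constant.  Sweeping Y0 produces a monotone family of trajectories:
stronger coupling, smaller metastasis.
"""

import numpy as np

from tumorgl import (
    GompertzParams,
    RadiationSchedule,
    SynergyParams,
    abscopal_trajectory,
)

gp_met = GompertzParams(a=0.054, k=0.0164, N0=50.0)
schedule = RadiationSchedule((9.0, 10.0, 11.0), (8.0, 8.0, 8.0), alpha=0.3, beta=0.03)
days = np.arange(0.0, 26.0, 1.0)

print("Y0 (day^-1)   day-15 size   day-25 size   (mm^3)")
for y0 in (0.0, 0.05, 0.1, 0.2, 0.4):
    syn = SynergyParams(delta=1.0, tau=2.0, Y0=y0, lag=2.0, t_in=9.0)
    traj = abscopal_trajectory(gp_met, syn, schedule, days)
    print(f"{y0:>8.2f}   {traj.sizes[days == 15][0]:>11.2f}   {traj.sizes[-1]:>11.2f}")

print("\nY0 = 0 reproduces untreated Gompertz growth exactly; increasing the")
print("coupling shrinks the metastasis pointwise, and strong coupling leaves a")
print("negative specific rate at the end of RT, after which the lesion decays")
print("exponentially at that frozen rate.")
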