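"""Pulse-train photoswitch kinetics: why the irradiation interval τ matters.

Expands three conditions sharing the same per-pulse dose (η = 0.022 W/cm²,
δ = 8 µs/px) but different intervals into pulse schedules, simulates the
photoswitch activity A(t) (jump per pulse, exponential dark reversion,
T_off = 30 min), and prints the time-averaged activity that drives
induction.
"""

import numpy as np

import optolight as ol
from optolight.simulate import photoswitch_activity, time_averaged_activity

t = np.arange(0.0, 1441.0)
print("condition  tau/min  pulses  time-averaged activity")
for label in ("7", "1", "6"):
    cond = ol.get_condition(label)
    sched = ol.make_schedule(cond, 1440.0)
    A = photoswitch_activity(sched, kappa=2.8, t_off_min=30.0, t_grid=t)
    abar = time_averaged_activity(A, t)
    print(f"{label:>9}  {cond.tau:7.0f}  {sched.n_pulses:6d}  {abar:.3f}")

print(
    "\nAt equal per-pulse dose, pulsing faster than the dark-reversion time "
    "keeps the switch near saturation (high average activity), while 60-min "
    "gaps let it relax almost fully between pulses — the mechanism behind "
    "the strong τ-dependence of induction."
)
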