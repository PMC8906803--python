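"""How faithfully does a 1.4-mm tracer follow an unsteady suction flow?

A reduced-order model of suction into a cylindrical mouth cavity (40 mm
long, 10 mm radius; 2 kPa suction ramped over 20 ms) advects a finite-size
particle with a reduced Maxey-Riley force balance and compares it against
the pure-fluid pathline released from the same point. Reported metrics:
velocity lag (during flow acceleration), overshoot (deceleration),
gravity-direction path deviation, and total path separation.
"""

import numpy as np

import oroflow as of
from oroflow.physics import SuctionModel, default_release_points, fidelity_of
from oroflow.trajectories import TracerSpec

model = SuctionModel()
print(f"{'rho (kg/m^3)':>12} {'release':>8} {'lag (m/s)':>10} "
      f"{'grav dev (mm)':>14} {'separation (mm)':>16}")
for density in (998.0, 1050.0, 1100.0, 1200.0):
    for i, rp in enumerate(default_release_points(model)):
        res = of.simulate_suction(model, TracerSpec(density=density), rp)
        rep = fidelity_of(res)
        print(f"{density:12.0f} {'rp' + str(i + 1):>8} {rep.max_lag:10.3f} "
              f"{rep.gravity_deviation * 1e3:14.3f} {rep.path_separation * 1e3:16.3f}")

print("\nA density-matched (998) particle tracks the flow almost perfectly;")
print("the heaviest usable tracers (~1050 kg/m^3) deviate along gravity by")
print("well under 1 mm during a strike, so the tracked paths report the")
print("water motion, not particle artifacts. Separation grows with density.")
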