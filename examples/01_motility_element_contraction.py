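"""Simulate the minimal contraction unit: two antiparallel microtubules
bridged by a two-headed kinesin multimer.

Both heads walk toward their filament's minus end at 0.3 units/s; because the
minus ends sit on opposite outer sides, the walk slides the filaments so
their overlap grows and the midpoints approach.
"""

import numpy as np

from mtmesh import SimConfig, build_motility_element, pair_gap, simulate

model = build_motility_element()  # length 4.0, diameter 0.2, overlap 1.0
traj = simulate(model, SimConfig())  # 200 frames at 1/24 s

gap = pair_gap(traj, "A", "B")
print(f"simulated duration : {traj.config.duration:.2f} s")
print(f"midpoint gap start : {gap[0]:.3f} sim units")
print(f"midpoint gap close : {gap.min():.3f} at frame {gap.argmin()}")
print(f"midpoint gap final : {gap[-1]:.3f}")
print(f"max rod residual   : {traj.residuals['rod'].max():.2e}")

# The gap shrinks from 3.015 to 0.300 (the lateral separation) by ~frame 126:
# the filaments are then fully abreast.  The motors keep walking, so the
# filaments continue to slide past each other and the gap regrows slightly;
# the run still ends well below its starting value.
assert gap[-1] < gap[0]
print("the kinesin multimer pulled the two filaments toward each other")

# Control: without the piston attachment the motor has no grip.
control = simulate(model, SimConfig(), disable=("piston",))
cgap = pair_gap(control, "A", "B")
print(f"no-piston control  : gap {cgap[0]:.3f} -> {cgap[-1]:.3f} (no contraction)")
assert cgap[-1] >= cgap[0] - 1e-9
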