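"""Simulate the published study protocols for one obese rat.

Builds the 12 h subcutaneous infusion protocol with abrupt stop, runs the
coupled exposure-insulin-FFA model at the published median parameters,
and prints the acute suppression and post-infusion rebound of FFA.
"""

import numpy as np

from niacffa import build_protocol, default_parameters, simulate_individual

pk, ins, ffa = default_parameters("obese")
protocol = build_protocol("Off_12h")
grid = np.linspace(0.0, 17.0, 341)
traj = simulate_individual(protocol, pk, ins, ffa, t_grid=grid)

F = traj["F"]
Cp = traj["Cp"]
print(f"plasma NiAc plateau:        {Cp.max():8.3f} uM   (endogenous {Cp.min():.4f} uM)")
print(f"baseline FFA:               {ffa.F0:8.3f} mM")
print(f"maximal FFA suppression:    {F.min():8.3f} mM   at t = {grid[F.argmin()]:.2f} h")
post = grid > 12.0
print(f"post-infusion FFA peak:     {F[post].max():8.3f} mM   at t = {grid[post][F[post].argmax()]:.2f} h")
print()
print("The infusion clamps NiAc near 1.3 uM; FFA drops sharply, then drifts")
print("back up as the moderator feedback develops tolerance.  Switching the")
print("pump off at 12 h produces the characteristic rebound above baseline.")
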