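"""Fit the Hertz contact model to a quasi-static force-distance curve.

Simulates a 3 um ramp with ~1 um indentation into an 800 Pa layer with
0.1 nN force noise and recovers the Young's modulus and contact point.
"""

from epimech import fit_youngs_modulus
from epimech.synthetic import simulate_force_curve

R = 12.5e-6  # 25 um bead
curve = simulate_force_curve(800.0, R, noise=0.1e-9, seed=3)
fit = fit_youngs_modulus(curve, R)

print(f"Young's modulus E = {fit.youngs_modulus:.1f} Pa (truth 800)")
print(f"contact point     = {fit.contact_point * 1e9:.1f} nm (truth 0)")
print(f"max indentation   = {fit.max_indentation * 1e6:.2f} um")
print(f"residual sum      = {fit.rss:.3e} N^2")
# The contact point is co-estimated with E, so the result is invariant to
# where the ramp starts and to any constant force baseline.
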