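"""Tricellular pulling forces and intercellular adhesive forces.

Measures a junction length from a synthetic fluorescence intensity profile,
converts tension + geometry into the pulling force at tricellular vertices,
and evaluates the normal/shear adhesive force balance on cell pairs of an
irregular hexagonal monolayer.
"""

import numpy as np

from epimech import adhesive_forces, junction_length_from_profile, pulling_force
from epimech.synthetic import simulate_hex_monolayer, simulate_junction_profile

# junction length from a noisy line profile (truth: 8 um between vertices)
profile = simulate_junction_profile(length=8.0e-6, noise=0.02, seed=4)
length = junction_length_from_profile(profile, smoothing_window=5)
print(f"junction length from intensity profile: {length * 1e6:.2f} um")

tension = 2.2e-3  # N/m, control-level apical tension
print(f"pulling force at that junction: {pulling_force(tension, length) * 1e9:.1f} nN")

pairs = simulate_hex_monolayer(mean_edge=7.3e-6, irregularity=0.2, n_pairs=14, seed=4)
normals = []
shears = []
for geom in pairs:
    forces = adhesive_forces(tension, geom)
    normals.append(forces.normal * 1e9)
    shears.append(forces.shear * 1e9)
print(
    f"adhesive forces over {len(pairs)} pairs: "
    f"F_NA = {np.mean(normals):+.1f} +/- {np.std(normals):.1f} nN, "
    f"F_SA = {np.mean(shears):+.1f} +/- {np.std(shears):.1f} nN"
)
# Perfectly regular hexagons balance exactly (both components zero); the
# 20% geometric irregularity produces adhesive forces of a few tens of nN,
# the scale needed to hold a cohesive monolayer together.
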