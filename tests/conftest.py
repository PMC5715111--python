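import numpy as np
import pytest

from epimech import CantileverCalibration, SimulationConfig
from epimech.synthetic import simulate_sweep_series


@pytest.fixture
def calib() -> CantileverCalibration:
    """Standard probe: 1 N/m cantilever, 25 um bead, aqueous medium, 35 kHz."""
    return CantileverCalibration(
        spring_constant=1.0,
        bead_radius=12.5e-6,
        fluid_viscosity=0.7e-3,
        f_far=35.0e3,
        drive_amplitude=10e-9,
    )


@pytest.fixture
def control_series(calib):
    """Noiseless series at control-like ground truth (T=2.2 nN/um, 1.8 mPa.s)."""
    return simulate_sweep_series(SimulationConfig(calibration=calib, seed=11))
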