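"""Apical effective viscosity from the phase-frequency slope.

With the tension known, dissipation in the monolayer surface layer is read
off the slope of the phase-frequency curve at resonance:

    mu_eff = -(12 T / R) * (lambda / h_m) / (pi * f_far**2 * dphi/df)

where ``lambda = sqrt(R h_m) / 2`` is the penetration depth of the
squeeze-film interaction into the substrate — the physical reason this
method probes only the top ~2.5 um of the epithelium.  The phase is taken
to decrease through resonance (dphi/df < 0), so a positive viscosity
requires a negative slope.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import CantileverCalibration, PhaseSlope, ViscosityResult
from .errors import DomainError, SignConventionError

logger = logging.getLogger(__name__)


def penetration_depth(bead_radius: float, h_m):
    """Depth scale lambda = sqrt(R h_m) / 2 probed by the squeeze film."""
    h_m = np.asarray(h_m, dtype=float)
    if not bead_radius > 0 or np.any(h_m <= 0):
        raise DomainError("bead radius and gap must be positive")
    return 0.5 * np.sqrt(bead_radius * h_m)


def effective_viscosity(
    tension: float,
    calib: CantileverCalibration,
    slope: PhaseSlope,
    f_far: float | None = None,
    allow_positive_slope: bool = False,
) -> ViscosityResult:
    """Effective viscosity of the apical layer from tension and phase slope.

    ``h_m`` in the formula is the gap at which the slope was measured
    (``slope.evaluation_gap``).  A positive slope violates the
    phase-decreasing convention and is rejected unless
    ``allow_positive_slope`` is set, in which case the (negative) result is
    returned flagged by its sign.
    """
    f_far = calib.f_far if f_far is None else f_far
    if f_far is None:
        raise DomainError("f_far is required (set it on the calibration or pass it)")
    if not tension > 0:
        raise DomainError("tension must be positive")
    if slope.slope == 0:
        raise DomainError("phase slope is zero; viscosity is undefined")
    if slope.slope > 0 and not allow_positive_slope:
        raise SignConventionError(
            "dphi/df > 0: the model assumes phase decreasing through resonance; "
            "negate phases on load (phase_increasing=True) or pass "
            "allow_positive_slope=True to keep the flagged negative result"
        )
    h_m = slope.evaluation_gap
    lam = float(penetration_depth(calib.bead_radius, h_m))
    mu_eff = (
        -(12.0 * tension / calib.bead_radius)
        * (lam / h_m)
        / (np.pi * f_far**2 * slope.slope)
    )
    logger.info(
        "effective viscosity: %.4g Pa.s (slope %.3g rad/Hz at %.0f nm)",
        mu_eff,
        slope.slope,
        h_m * 1e9,
    )
    return ViscosityResult(
        mu_eff=float(mu_eff),
        penetration_depth=lam,
        slope_used=slope.slope,
        evaluation_gap=h_m,
        tension_used=tension,
    )
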