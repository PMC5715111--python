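"""Apical epithelial tension from frequency-shift-versus-gap curves.

Squeeze-film lubrication of an oscillating microsphere above a prestressed
compliant monolayer predicts the resonance shift

    delta_f = (4 / (k_c R)) * sqrt(pi * f_far * h_m * T**3 / (6 mu))
              * (h_far / h_m - 1)

with ``k_c`` the cantilever spring constant, ``R`` the bead radius, ``mu``
the medium viscosity, ``h_m`` the probe-surface gap, ``h_far`` the
reference gap and ``T`` the isotropic apical tension.  The single free
parameter ``T`` is recovered by nonlinear least squares on the measured
(h_m, delta_f) points.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import least_squares

from .datatypes import CantileverCalibration, ShiftGapCurve, TensionFitResult
from .errors import DegenerateDataError, DomainError, FitError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MIN_GAP = 0.5e-6
DEFAULT_MAX_GAP = 6.0e-6


def predict_frequency_shift(
    calib: CantileverCalibration,
    tension: float,
    h_m,
    h_far: float,
    f_far: float | None = None,
):
    """Forward squeeze-film model: resonance shift at gap ``h_m`` (Hz).

    Vectorised over ``h_m``.  Zero at the reference gap; grows as the
    probe approaches the surface and as ``T**(3/2)``.
    """
    f_far = calib.f_far if f_far is None else f_far
    if f_far is None:
        raise DomainError("f_far is required (set it on the calibration or pass it)")
    h_m = np.asarray(h_m, dtype=float)
    if not tension > 0:
        raise DomainError("tension must be positive")
    if np.any(h_m <= 0) or np.any(h_m > h_far * (1 + 1e-12)):
        raise DomainError("gaps must satisfy 0 < h_m <= h_far")
    prefactor = 4.0 / (calib.spring_constant * calib.bead_radius)
    root = np.sqrt(
        np.pi * f_far * h_m * tension**3 / (6.0 * calib.fluid_viscosity)
    )
    return prefactor * root * (h_far / h_m - 1.0)


def initial_tension_estimate(
    calib: CantileverCalibration,
    shift: float,
    h_m: float,
    h_far: float,
    f_far: float | None = None,
) -> float:
    """Closed-form single-gap inversion of the shift formula, used to seed the fit."""
    f_far = calib.f_far if f_far is None else f_far
    if f_far is None:
        raise DomainError("f_far is required (set it on the calibration or pass it)")
    if not shift > 0:
        raise DomainError("shift must be positive to invert for tension")
    if not 0 < h_m < h_far:
        raise DomainError("h_m must satisfy 0 < h_m < h_far")
    geometric = shift * calib.spring_constant * calib.bead_radius / (
        4.0 * (h_far / h_m - 1.0)
    )
    return float(
        geometric ** (2.0 / 3.0)
        * (6.0 * calib.fluid_viscosity / (np.pi * f_far * h_m)) ** (1.0 / 3.0)
    )


def effective_probe_diameter(bead_radius: float, h_m):
    """Effective lateral probe size D_eff = 4 sqrt(R h_m).

    At gaps of 0.5-1 um with a 12.5 um bead this reaches ~10 um, i.e. the
    measurement averages over more than a single cell.
    """
    h_m = np.asarray(h_m, dtype=float)
    if not bead_radius > 0 or np.any(h_m <= 0):
        raise DomainError("bead radius and gap must be positive")
    return 4.0 * np.sqrt(bead_radius * h_m)


def fit_tension(
    curve: ShiftGapCurve,
    calib: CantileverCalibration,
    min_gap: float = DEFAULT_MIN_GAP,
    max_gap: float = DEFAULT_MAX_GAP,
    fit_offset: bool = False,
) -> TensionFitResult:
    """Nonlinear least-squares fit of the apical tension to a shift-gap curve.

    Parameters
    ----------
    curve
        Measured (gap, shift) points with their reference frequency.
    calib
        Probe constants; ``f_far`` is taken from the curve, not the
        calibration, so the reference is always per-measurement.
    min_gap, max_gap
        Only points with ``min_gap <= h <= max_gap`` enter the fit.
    fit_offset
        Diagnostic mode co-fitting a global gap offset ``dh`` (h -> h + dh)
        to probe contact-point error; off by default.

    The standard error comes from the linearised Jacobian at the optimum
    with the residual variance estimated from the fit.
    """
    keep = (curve.gaps >= min_gap * (1 - 1e-12)) & (curve.gaps <= max_gap * (1 + 1e-12))
    gaps = curve.gaps[keep]
    shifts = curve.shifts[keep]
    n_params = 2 if fit_offset else 1
    if len(gaps) < max(3, n_params + 1):
        raise ValidationError(
            f"only {len(gaps)} points inside [{min_gap * 1e9:.0f}, "
            f"{max_gap * 1e9:.0f}] nm; need at least {max(3, n_params + 1)}"
        )
    if np.all(shifts <= 0):
        raise DegenerateDataError("all frequency shifts are zero or negative; no signal to fit")

    smallest = np.argmin(gaps)
    t0 = initial_tension_estimate(
        calib, float(shifts[smallest]), float(gaps[smallest]), curve.h_far, curve.f_far
    )

    def residual_fn(params: np.ndarray) -> np.ndarray:
        tension = params[0]
        offset = params[1] if fit_offset else 0.0
        h_eff = np.clip(gaps + offset, 1e-12, None)
        h_far_eff = curve.h_far + offset
        pred = predict_frequency_shift(calib, tension, h_eff, h_far_eff, curve.f_far)
        return shifts - pred

    x0 = np.array([t0, 0.0][:n_params])
    lower = np.array([1e-15, -min_gap / 2][:n_params])
    upper = np.array([np.inf, min_gap / 2][:n_params])

    result = None
    for scale in (1.0, 0.1, 10.0):
        trial = x0.copy()
        trial[0] = t0 * scale
        sol = least_squares(residual_fn, trial, bounds=(lower, upper), xtol=1e-14, ftol=1e-14)
        if sol.success and (result is None or sol.cost < result.cost):
            result = sol
    if result is None:
        raise FitError("tension fit did not converge after bounded restarts")

    residuals = result.fun
    rss = float(np.sum(residuals**2))
    dof = max(len(gaps) - n_params, 1)
    jtj = result.jac.T @ result.jac
    try:
        cov = np.linalg.inv(jtj) * rss / dof
        se = float(np.sqrt(cov[0, 0]))
    except np.linalg.LinAlgError:
        se = float("nan")

    tension = float(result.x[0])
    offset = float(result.x[1]) if fit_offset else 0.0
    logger.info(
        "tension fit: T = %.4g N/m (SE %.2g), rss = %.3g Hz^2, n = %d",
        tension,
        se,
        rss,
        len(gaps),
    )
    return TensionFitResult(
        tension=tension,
        standard_error=se,
        residuals=residuals,
        rss=rss,
        n_points=len(gaps),
        effective_probe_diameters=effective_probe_diameter(calib.bead_radius, gaps),
        gap_offset=offset,
    )
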