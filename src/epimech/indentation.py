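"""Hertz-model analysis of quasi-static indentation force curves.

A rigid sphere of radius ``R`` indenting an isotropic elastic half-space
obeys

    F = (4/3) * E / (1 - nu**2) * sqrt(R) * delta**(3/2)

with indentation depth ``delta`` and Poisson ratio ``nu`` (0.5 for an
incompressible cell layer).  ``fit_youngs_modulus`` estimates ``E`` and the
contact point jointly after subtracting the pre-contact force baseline; no
finite-thickness (bottom-effect) correction is applied.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import minimize_scalar

from .datatypes import ForceCurve, HertzFitResult
from .errors import ContactNotFoundError, DomainError, FitError

logger = logging.getLogger(__name__)

DEFAULT_MAX_INDENTATION = 1.0e-6


def hertz_force(youngs_modulus: float, poisson_ratio: float, bead_radius: float, delta):
    """Hertz contact force (N) of a sphere at indentation ``delta`` (vectorised)."""
    delta = np.asarray(delta, dtype=float)
    if not 0 <= poisson_ratio < 1:
        raise DomainError("Poisson ratio must lie in [0, 1)")
    if not youngs_modulus > 0 or not bead_radius > 0:
        raise DomainError("modulus and radius must be positive")
    if np.any(delta < 0):
        raise DomainError("indentation must be non-negative")
    return (
        (4.0 / 3.0)
        * youngs_modulus
        / (1.0 - poisson_ratio**2)
        * np.sqrt(bead_radius)
        * delta**1.5
    )


def fit_youngs_modulus(
    curve: ForceCurve,
    bead_radius: float,
    poisson_ratio: float = 0.5,
    max_indentation: float = DEFAULT_MAX_INDENTATION,
) -> HertzFitResult:
    """Young's modulus and contact point from one force-distance curve.

    The baseline force (mean over the farthest 25% of separations) is
    subtracted first; the contact point is then located where the force
    rises above the baseline noise and refined jointly with ``E`` by least
    squares on the piecewise model (zero before contact, Hertz after).
    Points deeper than ``max_indentation`` past the initial contact guess
    are excluded, matching an analysis restricted to ~1 um indentations.
    """
    if not bead_radius > 0:
        raise DomainError("bead radius must be positive")
    order = np.argsort(curve.separations)[::-1]  # far to deep
    sep = curve.separations[order]
    force = curve.forces[order]

    n_base = max(len(sep) // 4, 2)
    baseline = float(np.mean(force[:n_base]))
    noise = float(np.std(force[:n_base]))
    force = force - baseline

    threshold = max(5.0 * noise, 1e-4 * float(np.max(np.abs(force)) or 1.0))
    above = force > threshold
    if above.sum() < 10:
        raise ContactNotFoundError(
            "no contact regime detected: fewer than 10 samples rise above the "
            "baseline noise"
        )
    # initial contact: farthest separation whose force exceeds the threshold
    contact0 = float(sep[np.argmax(above)])
    keep = sep > contact0 - max_indentation
    sep_fit = sep[keep]
    force_fit = force[keep]

    # E enters linearly, so profile it out and search the contact point alone:
    # for each candidate contact c the optimal modulus is a closed-form
    # linear-least-squares ratio, leaving a smooth 1-D objective in c.
    shape = (4.0 / 3.0) / (1.0 - poisson_ratio**2) * np.sqrt(bead_radius)

    def profiled(c: float) -> tuple[float, float]:
        delta = np.clip(c - sep_fit, 0.0, None)
        basis = shape * delta**1.5
        denom = float(basis @ basis)
        if denom == 0:
            return 0.0, float(force_fit @ force_fit)
        e_hat = max(float((basis @ force_fit) / denom), 0.0)
        resid = force_fit - e_hat * basis
        return e_hat, float(resid @ resid)

    # threshold crossing detects contact late (deeper than truth), so search
    # mostly upward from the initial guess
    lo = contact0 - 0.05e-6
    hi = float(min(contact0 + 0.5e-6, sep_fit.max()))
    sol = minimize_scalar(lambda c: profiled(c)[1], bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-13})
    if not sol.success:
        raise FitError("Hertz contact-point search did not converge")
    contact = float(sol.x)
    youngs_modulus, rss = profiled(contact)
    if youngs_modulus <= 0:
        raise FitError("Hertz fit collapsed to a non-positive modulus")
    max_delta = float(np.clip(contact - sep_fit.min(), 0.0, None))
    logger.info(
        "Hertz fit: E = %.4g Pa, contact at %.1f nm, rss = %.3g N^2",
        youngs_modulus,
        contact * 1e9,
        rss,
    )
    return HertzFitResult(
        youngs_modulus=youngs_modulus,
        poisson_ratio=poisson_ratio,
        contact_point=contact,
        rss=rss,
        max_indentation=max_delta,
    )
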