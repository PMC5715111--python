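"""Tricellular pulling forces and intercellular adhesive forces.

Actomyosin contraction along the lateral walls of hexagonally packed cells
pulls on each tricellular vertex with a force set by the apical tension and
the edge length,

    f = sqrt(3) * T * l.

A force balance on a shared cell-cell contact flanked by two tricellular
junctions resolves the intercellular adhesive force into components normal
and tangential to the contact:

    F_NA = sqrt(3) T (l2 cos t2 + l4 cos t4 - l1 cos t1 - l3 cos t3)
    F_SA = sqrt(3) T (l1 sin t1 + l2 sin t2 - l3 sin t3 - l4 sin t4)

with ``l_i``/``theta_i`` the flanking edge lengths and angles (measured
from the contact normal, i.e. raw inter-line angle minus 90 degrees).  Both
vanish for a perfectly symmetric pair.  Junction lengths are measured from
fluorescence intensity profiles as the distance between the extrema of the
forward-difference derivative.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import HALF_PI, AdhesionForces, IntensityProfile, JunctionGeometry
from .errors import DomainError, VertexNotFoundError

logger = logging.getLogger(__name__)

SQRT3 = np.sqrt(3.0)
DEFAULT_SMOOTHING_WINDOW = 5


def pulling_force(tension: float, edge_length: float) -> float:
    """Myosin pulling force at a tricellular junction: sqrt(3) * T * l."""
    if tension < 0 or edge_length < 0:
        raise DomainError("tension and edge length must be non-negative")
    return SQRT3 * tension * edge_length


def adhesive_forces(tension: float, geometry: JunctionGeometry) -> AdhesionForces:
    """Normal and shear intercellular adhesive forces for one cell pair.

    Both components are linear in the tension; their signs encode the
    direction of the net imbalance across the shared contact.
    """
    if not tension > 0:
        raise DomainError("tension must be positive")
    l1, l2, l3, l4 = geometry.flanking_lengths
    t1, t2, t3, t4 = geometry.flanking_angles
    normal = SQRT3 * tension * (
        l2 * np.cos(t2) + l4 * np.cos(t4) - l1 * np.cos(t1) - l3 * np.cos(t3)
    )
    shear = SQRT3 * tension * (
        l1 * np.sin(t1) + l2 * np.sin(t2) - l3 * np.sin(t3) - l4 * np.sin(t4)
    )
    return AdhesionForces(
        pulling_force=pulling_force(tension, geometry.shared_edge_length),
        normal=float(normal),
        shear=float(shear),
        tension_used=tension,
        pair_id=geometry.pair_id,
    )


def _extremum_position(midpoints: np.ndarray, diffs: np.ndarray, sign: float) -> float:
    """Mean midpoint position of the tied extreme forward differences.

    Linear ramps give a plateau of equal differences; averaging the tied
    positions lands on the ramp centre, making trapezoidal profiles exact.
    """
    values = sign * diffs
    best = values.max()
    if best <= 0:
        raise VertexNotFoundError(
            "profile lacks a derivative extremum of the required sign"
        )
    tol = max(abs(best) * 1e-9, 1e-30)
    return float(np.mean(midpoints[values >= best - tol]))


def junction_length_from_profile(
    profile: IntensityProfile,
    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
) -> float:
    """Junction length as the distance between derivative extrema.

    The forward difference of the intensity profile approximates the
    derivative; each difference is assigned to the midpoint of its sample
    interval.  An optional centred moving average (``smoothing_window``
    samples, 1 = off) suppresses noise before locating the positive and
    negative extrema, whose separation is the junction length.
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise DomainError("smoothing_window must be a positive odd integer")
    diffs = np.diff(profile.intensities)
    midpoints = (profile.positions[:-1] + profile.positions[1:]) / 2.0
    if smoothing_window > 1:
        if smoothing_window >= len(diffs):
            raise DomainError("smoothing_window is larger than the profile derivative")
        kernel = np.ones(smoothing_window) / smoothing_window
        half = smoothing_window // 2
        diffs = np.convolve(diffs, kernel, mode="valid")
        midpoints = midpoints[half : len(midpoints) - half]

    rise = _extremum_position(midpoints, diffs, +1.0)
    fall = _extremum_position(midpoints, diffs, -1.0)
    length = abs(fall - rise)
    if length < 2 * profile.spacing:
        raise VertexNotFoundError(
            "derivative extrema are not well separated; no junction span detected"
        )
    logger.info("junction length from profile: %.3f um", length * 1e6)
    return length


def edge_angle(contact_direction, edge_direction) -> float:
    """Angle of a cell edge measured from the contact normal.

    Both directions are undirected lines; the angle between them is reduced
    to [0, pi/2] and the edge angle is its deviation from perpendicularity,
    ``theta = pi/2 - angle_between_lines``, equivalently the magnitude of
    the raw inter-line angle minus 90 degrees for either choice of interior
    angle.  An edge parallel to the contact (theta = pi/2) is degenerate
    and rejected.
    """
    u = np.asarray(contact_direction, dtype=float)
    v = np.asarray(edge_direction, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DomainError("direction vectors must be nonzero")
    cos_between = abs(float(np.dot(u, v)) / (nu * nv))
    between = float(np.arccos(np.clip(cos_between, 0.0, 1.0)))  # in [0, pi/2]
    theta = HALF_PI - between
    if theta >= HALF_PI - 1e-12:
        raise DomainError("edge is parallel to the contact; angle is degenerate")
    return theta
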