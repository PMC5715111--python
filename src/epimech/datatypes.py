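"""Domain containers for the FM-AFM epithelial-mechanics pipeline.

All in-memory quantities are SI (metres, newtons, radians, hertz, Pa·s);
the file layer converts from/to the nm / nN / degree units used on disk.
Containers validate their physical invariants on construction and raise
:class:`~epimech.errors.ValidationError` (or a subclass) when violated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError, ValidationError

HALF_PI = np.pi / 2.0


def _as_float_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass
class CantileverCalibration:
    """Probe constants shared by all spectro-mechanical operations.

    Parameters
    ----------
    spring_constant : float
        Cantilever spring constant ``k_c`` in N/m.
    bead_radius : float
        Radius ``R`` of the attached microsphere in m.
    fluid_viscosity : float
        Dynamic viscosity ``mu`` of the immersion medium in Pa·s.
    f_far : float, optional
        pi/2-phase resonance frequency (Hz) at the reference gap.  May be
        left unset and taken from the reference sweep of a series.
    drive_amplitude : float, optional
        Piezo drive amplitude in m.  Metadata only; the squeeze-film model
        assumes it is small compared with every analysed gap.
    """

    spring_constant: float
    bead_radius: float
    fluid_viscosity: float
    f_far: float | None = None
    drive_amplitude: float | None = None

    def __post_init__(self) -> None:
        for name in ("spring_constant", "bead_radius", "fluid_viscosity"):
            if not getattr(self, name) > 0:
                raise DomainError(f"calibration {name} must be positive")
        if self.f_far is not None and not self.f_far > 0:
            raise DomainError("calibration f_far must be positive when given")
        if self.drive_amplitude is not None and not self.drive_amplitude > 0:
            raise DomainError("calibration drive_amplitude must be positive when given")


@dataclass
class FrequencySweep:
    """Phase (and optionally amplitude) versus drive frequency at one gap."""

    gap_height: float
    frequencies: np.ndarray
    phases: np.ndarray
    amplitudes: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.gap_height > 0:
            raise ValidationError("sweep gap_height must be positive")
        self.frequencies = _as_float_array(self.frequencies, "frequencies")
        self.phases = _as_float_array(self.phases, "phases")
        if len(self.phases) != len(self.frequencies):
            raise ValidationError("phases and frequencies must have equal length")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValidationError(
                f"frequencies must be strictly increasing (gap "
                f"{self.gap_height * 1e9:.0f} nm)"
            )
        if self.amplitudes is not None:
            self.amplitudes = _as_float_array(self.amplitudes, "amplitudes")
            if len(self.amplitudes) != len(self.frequencies):
                raise ValidationError("amplitudes and frequencies must have equal length")

    def crosses_half_pi(self) -> bool:
        """Whether the phase record brackets pi/2 (required for f_pi/2)."""
        return bool(self.phases.min() < HALF_PI < self.phases.max())


@dataclass
class SweepSeries:
    """Frequency sweeps at a ladder of gaps plus the shared calibration.

    The reference gap ``h_far`` anchors the frequency-shift definition:
    shifts are measured relative to the pi/2 frequency at ``h_far``.
    """

    calibration: CantileverCalibration
    sweeps: list[FrequencySweep]
    reference_gap: float

    def __post_init__(self) -> None:
        if not self.sweeps:
            raise ValidationError("series contains no sweeps")
        gaps = np.array([s.gap_height for s in self.sweeps])
        if len(np.unique(gaps)) != len(gaps):
            raise ValidationError("sweep gaps must be unique")
        if np.sum(np.isclose(gaps, self.reference_gap, rtol=1e-12)) != 1:
            raise ValidationError("exactly one sweep must sit at the reference gap")
        if np.any(gaps > self.reference_gap * (1 + 1e-12)):
            raise ValidationError("all gaps must be <= the reference gap")
        # canonical order: farthest first, mirroring the approach protocol
        self.sweeps = sorted(self.sweeps, key=lambda s: -s.gap_height)

    @property
    def gaps(self) -> np.ndarray:
        return np.array([s.gap_height for s in self.sweeps])

    def sweep_at(self, gap: float, rtol: float = 1e-9) -> FrequencySweep | None:
        for s in self.sweeps:
            if np.isclose(s.gap_height, gap, rtol=rtol):
                return s
        return None

    @property
    def reference_sweep(self) -> FrequencySweep:
        sweep = self.sweep_at(self.reference_gap)
        assert sweep is not None
        return sweep


@dataclass
class ForceCurve:
    """Quasi-static separation/force record from an indentation ramp."""

    separations: np.ndarray
    forces: np.ndarray

    def __post_init__(self) -> None:
        self.separations = _as_float_array(self.separations, "separations")
        self.forces = _as_float_array(self.forces, "forces")
        if len(self.separations) != len(self.forces):
            raise ValidationError("separations and forces must have equal length")
        if len(self.separations) < 2:
            raise ValidationError("force curve needs at least two samples")


@dataclass
class ShiftGapCurve:
    """The (gap, frequency shift) observable fitted for tension."""

    gaps: np.ndarray
    shifts: np.ndarray
    f_far: float
    h_far: float

    def __post_init__(self) -> None:
        self.gaps = _as_float_array(self.gaps, "gaps")
        self.shifts = _as_float_array(self.shifts, "shifts")
        if len(self.gaps) != len(self.shifts):
            raise ValidationError("gaps and shifts must have equal length")
        if not self.f_far > 0:
            raise DomainError("f_far must be positive")
        if not self.h_far > 0:
            raise DomainError("h_far must be positive")
        at_ref = np.isclose(self.gaps, self.h_far, rtol=1e-12)
        if at_ref.any() and not np.allclose(self.shifts[at_ref], 0.0, atol=1e-9):
            raise ValidationError("shift at the reference gap must be zero")


@dataclass
class PhaseSlope:
    """Slope of the phase-frequency curve at the pi/2 crossing of one sweep."""

    slope: float
    evaluation_gap: float
    fit_window: tuple[float, float]

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValidationError("phase slope must be finite")
        if not self.evaluation_gap > 0:
            raise DomainError("evaluation_gap must be positive")


@dataclass
class TensionFitResult:
    """Apical epithelial tension from the shift-gap nonlinear fit.

    ``caveat`` records the documented approximation that viscoelastic
    dissipation is neglected (it perturbs the tension by <10%).
    """

    tension: float
    standard_error: float
    residuals: np.ndarray
    rss: float
    n_points: int
    effective_probe_diameters: np.ndarray
    gap_offset: float = 0.0
    caveat: str = (
        "Viscoelastic dissipation of the monolayer is neglected; the "
        "tension estimate is perturbed by less than about 10%."
    )

    def __post_init__(self) -> None:
        if not self.tension > 0:
            raise DomainError("fitted tension must be positive")
        if self.n_points < 3:
            raise ValidationError("tension fit needs at least 3 points")
        self.residuals = _as_float_array(self.residuals, "residuals")
        self.effective_probe_diameters = _as_float_array(
            self.effective_probe_diameters, "effective_probe_diameters"
        )

    @property
    def tension_nN_per_um(self) -> float:
        """Tension in the reporting unit nN/µm (= mN/m)."""
        return self.tension * 1e3


@dataclass
class ViscosityResult:
    """Apical effective viscosity from tension and the phase slope."""

    mu_eff: float
    penetration_depth: float
    slope_used: float
    evaluation_gap: float
    tension_used: float

    @property
    def mu_eff_mPa_s(self) -> float:
        return self.mu_eff * 1e3


@dataclass
class HertzFitResult:
    """Young's modulus from a spherical-indenter Hertz fit."""

    youngs_modulus: float
    poisson_ratio: float
    contact_point: float
    rss: float
    max_indentation: float

    def __post_init__(self) -> None:
        if not self.youngs_modulus > 0:
            raise DomainError("fitted Young's modulus must be positive")
        if not 0 <= self.poisson_ratio < 1:
            raise DomainError("Poisson ratio must lie in [0, 1)")


@dataclass
class JunctionGeometry:
    """Edge lengths and angles of one hexagonal cell pair.

    The shared cell-cell contact has length ``l``; the four flanking edges
    ``l1..l4`` meet the contact at angles ``theta1..theta4`` measured from
    the contact normal (the raw inter-line angle minus 90 degrees), each in
    [0, pi/2).
    """

    shared_edge_length: float
    flanking_lengths: tuple[float, float, float, float]
    flanking_angles: tuple[float, float, float, float]
    pair_id: str = ""

    def __post_init__(self) -> None:
        lengths = (self.shared_edge_length, *self.flanking_lengths)
        if any(not l > 0 for l in lengths):
            raise ValidationError(f"junction lengths must be positive (pair {self.pair_id!r})")
        for theta in self.flanking_angles:
            if not (0 <= theta < HALF_PI):
                raise ValidationError(
                    f"edge angle {np.degrees(theta):.1f} deg outside [0, 90) "
                    f"(pair {self.pair_id!r}); angles are post 90-degree subtraction"
                )


@dataclass
class AdhesionForces:
    """Tricellular pulling force and intercellular adhesive components."""

    pulling_force: float
    normal: float
    shear: float
    tension_used: float
    pair_id: str = ""


@dataclass
class IntensityProfile:
    """Uniformly sampled 1-D fluorescence intensity along a junction-parallel line."""

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.positions = _as_float_array(self.positions, "positions")
        self.intensities = _as_float_array(self.intensities, "intensities")
        if len(self.positions) != len(self.intensities):
            raise ValidationError("positions and intensities must have equal length")
        if len(self.positions) < 8:
            raise ValidationError("intensity profile needs at least 8 samples")
        steps = np.diff(self.positions)
        if np.any(steps <= 0):
            raise ValidationError("positions must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9):
            raise ValidationError("positions must be uniformly spaced")

    @property
    def spacing(self) -> float:
        return float(self.positions[1] - self.positions[0])


@dataclass
class GroupSummary:
    """Mean +/- SD summary of one experimental group."""

    label: str
    n: int
    mean: float
    sd: float
    unit: str = ""

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("group must contain at least one value")
        if self.sd < 0:
            raise ValidationError("sd must be non-negative")
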