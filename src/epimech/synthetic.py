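"""Forward simulators with known ground truth.

Every analysis step in the package has a generator here that produces data
from the same physics the estimators invert: damped-oscillator phase
responses whose resonance ladder follows the squeeze-film shift formula,
Hertzian indentation curves, hexagonal cell-pair geometry tables, and
trapezoidal junction intensity profiles.  Outputs pass the corresponding
readers' validators, so simulate -> write -> read -> analyse is the
canonical round-trip test path.

Randomness is counter-based: one global seed is combined with per-sweep
indices, so adding sweeps to a config never reshuffles existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    CantileverCalibration,
    ForceCurve,
    FrequencySweep,
    IntensityProfile,
    JunctionGeometry,
    SweepSeries,
)
from .errors import ConfigError, DomainError
from .indentation import hertz_force
from .tension import predict_frequency_shift
from .viscosity import penetration_depth

DEFAULT_GAP_LADDER = tuple(np.arange(6.0e-6, 0.4e-6, -0.5e-6))  # 6 -> 0.5 um, 500 nm steps
DEFAULT_SAMPLES_PER_SWEEP = 401
DEFAULT_SWEEP_SPAN = 10.0e3  # Hz, sweep width around the resonance

DEFAULT_CALIBRATION = CantileverCalibration(
    spring_constant=1.0,  # N/m, inside the 0.7-1.5 N/m cantilever range
    bead_radius=12.5e-6,  # m, 25 um bead
    fluid_viscosity=0.7e-3,  # Pa.s, aqueous medium at 37 C
    f_far=35.0e3,  # Hz, within the typical 32-38 kHz natural-frequency band
    drive_amplitude=10e-9,  # m, small-amplitude regime
)


def _rng(seed: int, *counters: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *map(int, counters)])


@dataclass
class SimulationConfig:
    """Ground truth and noise model for a simulated sweep series.

    Defaults reproduce the study conditions: control-level tension
    2.2 nN/um and effective viscosity 1.8 mPa.s, a 12-gap ladder from 6 um
    to 500 nm in 500 nm steps, and 401 samples over a 10 kHz span per
    sweep.  When ``viscosity_eff`` is set, the local oscillator quality
    factor at each gap is derived from the slope the viscosity relation
    demands there, so the full pipeline is invertible; otherwise
    ``quality_factor`` is used everywhere.
    """

    tension: float = 2.2e-3  # N/m
    viscosity_eff: float | None = 1.8e-3  # Pa.s
    quality_factor: float = 3.0
    calibration: CantileverCalibration = field(
        default_factory=lambda: DEFAULT_CALIBRATION
    )
    gap_ladder: tuple[float, ...] = DEFAULT_GAP_LADDER
    samples_per_sweep: int = DEFAULT_SAMPLES_PER_SWEEP
    sweep_span: float = DEFAULT_SWEEP_SPAN
    phase_noise: float = 0.0  # rad
    shift_noise: float = 0.0  # Hz
    spurious_peaks: tuple[tuple[float, float, float], ...] = ()  # (freq, rel amp, width)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tension < 0:
            raise ConfigError("tension must be non-negative")
        if self.viscosity_eff is not None and not self.viscosity_eff > 0:
            raise ConfigError("viscosity_eff must be positive when given")
        if not self.quality_factor > 0:
            raise ConfigError("quality_factor must be positive")
        if self.calibration.f_far is None:
            raise ConfigError("calibration must carry f_far for simulation")
        if len(self.gap_ladder) == 0:
            raise ConfigError("gap ladder is empty")
        if self.samples_per_sweep < 8:
            raise ConfigError("samples_per_sweep must be at least 8")
        if self.phase_noise < 0 or self.shift_noise < 0:
            raise ConfigError("noise levels must be non-negative")


def _local_quality_factor(config: SimulationConfig, gap: float, f0: float) -> float:
    """Quality factor that encodes the target effective viscosity at this gap."""
    if config.viscosity_eff is None or config.tension == 0:
        return config.quality_factor
    calib = config.calibration
    lam = float(penetration_depth(calib.bead_radius, gap))
    slope = -12.0 * config.tension * lam / (
        calib.bead_radius * gap * np.pi * calib.f_far**2 * config.viscosity_eff
    )
    q_local = -slope * f0 / 2.0
    if not q_local > 0:
        raise ConfigError(
            f"target viscosity implies non-positive quality factor {q_local:.3g} "
            f"at gap {gap * 1e9:.0f} nm"
        )
    return q_local


def _sho_phase(freqs: np.ndarray, f0: float, q: float) -> np.ndarray:
    """Damped-oscillator phase, pi/2 at f0 and decreasing with frequency."""
    return np.pi - np.arctan2(freqs * f0 / q, f0**2 - freqs**2)


def _sho_amplitude(freqs: np.ndarray, f0: float, q: float) -> np.ndarray:
    response = 1.0 / np.sqrt((f0**2 - freqs**2) ** 2 + (freqs * f0 / q) ** 2)
    return response / response.max()


def simulate_sweep_series(config: SimulationConfig) -> SweepSeries:
    """Generate a sweep series whose resonance ladder follows the shift formula.

    Each gap's resonance is ``f_far + delta_f(h)``; the phase slope at the
    resonance encodes the target effective viscosity.  Gaussian shift noise
    perturbs the resonance, phase noise perturbs each phase sample; both
    are reproducible from the seed, per sweep.
    """
    calib = config.calibration
    h_far = max(config.gap_ladder)
    sweeps = []
    for index, gap in enumerate(sorted(config.gap_ladder, reverse=True)):
        if config.tension > 0:
            shift = float(
                predict_frequency_shift(calib, config.tension, gap, h_far)
            )
        else:
            shift = 0.0
        f0 = calib.f_far + shift
        if config.shift_noise > 0 and not np.isclose(gap, h_far):
            f0 += config.shift_noise * _rng(config.seed, index, 0).standard_normal()
        q_local = _local_quality_factor(config, gap, f0)
        freqs = np.linspace(
            f0 - config.sweep_span / 2, f0 + config.sweep_span / 2, config.samples_per_sweep
        )
        phases = _sho_phase(freqs, f0, q_local)
        if config.phase_noise > 0:
            phases = phases + config.phase_noise * _rng(
                config.seed, index, 1
            ).standard_normal(len(freqs))
        amplitudes = _sho_amplitude(freqs, f0, q_local)
        for peak_f, rel_amp, width in config.spurious_peaks:
            amplitudes = amplitudes + rel_amp / (1.0 + ((freqs - peak_f) / width) ** 2)
        sweeps.append(
            FrequencySweep(
                gap_height=gap, frequencies=freqs, phases=phases, amplitudes=amplitudes
            )
        )
    return SweepSeries(calibration=calib, sweeps=sweeps, reference_gap=h_far)


def simulate_force_curve(
    youngs_modulus: float,
    bead_radius: float,
    contact: float = 0.0,
    noise: float = 0.0,
    seed: int = 0,
    poisson_ratio: float = 0.5,
    approach: float = 2.0e-6,
    depth: float = 1.0e-6,
    n_samples: int = 601,
) -> ForceCurve:
    """Hertzian force-distance curve: flat baseline, then a 3/2-power rise.

    The ramp spans ``contact + approach`` down to ``contact - depth``
    (3 um total by default), with seeded Gaussian force noise.
    """
    if not youngs_modulus > 0:
        raise DomainError("Young's modulus must be positive")
    separations = np.linspace(contact + approach, contact - depth, n_samples)
    delta = np.clip(contact - separations, 0.0, None)
    forces = hertz_force(youngs_modulus, poisson_ratio, bead_radius, delta)
    if noise > 0:
        forces = forces + noise * _rng(seed, 0).standard_normal(n_samples)
    return ForceCurve(separations=separations, forces=forces)


REGULAR_HEX_ANGLE = np.radians(30.0)  # 120 deg interior angle, minus 90 from the normal


def simulate_hex_monolayer(
    mean_edge: float = 7.3e-6,
    irregularity: float = 0.0,
    n_pairs: int = 14,
    seed: int = 0,
) -> list[JunctionGeometry]:
    """Geometry tables for cell pairs in a hexagonal monolayer.

    ``irregularity = 0`` gives perfectly regular hexagons (all edges equal,
    all flanking angles 30 degrees), for which the adhesive forces vanish
    identically.  A fraction ``irregularity`` perturbs each length and
    angle by an independent seeded uniform factor of that relative size,
    respecting the geometric invariants.  The default edge length matches
    control monolayers; the default ``n_pairs`` matches the per-condition
    sample size of the junction-force estimates.
    """
    if not 0 <= irregularity < 1:
        raise DomainError("irregularity must lie in [0, 1)")
    if n_pairs < 1:
        raise DomainError("n_pairs must be positive")
    geometries = []
    for index in range(n_pairs):
        rng = _rng(seed, index)
        perturb = lambda x: x * (1.0 + irregularity * rng.uniform(-1.0, 1.0))
        angles = tuple(
            float(np.clip(perturb(REGULAR_HEX_ANGLE), 0.0, np.pi / 2 - 1e-9))
            for _ in range(4)
        )
        geometries.append(
            JunctionGeometry(
                shared_edge_length=perturb(mean_edge),
                flanking_lengths=tuple(perturb(mean_edge) for _ in range(4)),
                flanking_angles=angles,
                pair_id=f"pair{index:03d}",
            )
        )
    return geometries


def simulate_junction_profile(
    length: float = 8.0e-6,
    ramp_width: float = 1.0e-6,
    noise: float = 0.0,
    seed: int = 0,
    spacing: float = 50.0e-9,
    padding: float = 2.0e-6,
    low: float = 100.0,
    high: float = 1000.0,
) -> IntensityProfile:
    """Trapezoidal fluorescence profile across a junction of known length.

    The distance between the midpoints of the rising and falling ramps
    (i.e. between the forward-difference extrema) equals ``length``
    exactly in the noiseless case.
    """
    if not 0 < ramp_width < length:
        raise DomainError("need 0 < ramp_width < length")
    plateau = length - ramp_width
    total = 2 * padding + 2 * ramp_width + plateau
    n = int(round(total / spacing)) + 1
    positions = np.arange(n) * spacing
    x1 = padding  # start of rise
    x2 = padding + ramp_width
    x3 = x2 + plateau
    x4 = x3 + ramp_width
    intensities = np.interp(positions, [0, x1, x2, x3, x4, total], [low, low, high, high, low, low])
    if noise > 0:
        intensities = intensities + noise * (high - low) * _rng(seed, 0).standard_normal(n)
    return IntensityProfile(positions=positions, intensities=intensities)
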