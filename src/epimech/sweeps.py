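"""Per-sweep feature extraction: pi/2 resonance, frequency shifts, phase slope.

The FM-AFM protocol tracks the drive frequency at which the piezo-to-
cantilever phase lag equals pi/2 (the operational resonance f_pi/2).  As the
oscillating microsphere approaches the apical surface, squeeze-film coupling
pushes f_pi/2 upward; the resulting shift-versus-gap curve is the observable
for the tension fit, and the local slope dphi/df feeds the effective
viscosity.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from numpy.polynomial import Polynomial

from .datatypes import HALF_PI, FrequencySweep, PhaseSlope, ShiftGapCurve, SweepSeries
from .errors import (
    ExtractionError,
    InsufficientDataError,
    PeakNotFoundError,
)

logger = logging.getLogger(__name__)

DEFAULT_PI2_WINDOW = 0.3  # rad; samples with |phase - pi/2| below this enter the fit
DEFAULT_SLOPE_WINDOW = 0.5  # rad; wider window for the cubic slope fit
DEFAULT_SLOPE_GAP = 2.0e-6  # m; gap at which dphi/df is evaluated


def extract_f_pi2(sweep: FrequencySweep, window_halfwidth: float = DEFAULT_PI2_WINDOW) -> float:
    """Frequency at which the phase crosses pi/2, from a local quadratic fit.

    A second-order polynomial phase(f) is fitted to the samples with
    ``|phase - pi/2| <= window_halfwidth`` and solved for phase = pi/2.  Of
    the real roots, the one closest to the sample frequency nearest the
    crossing is returned; it must lie inside the sweep's frequency range.
    """
    if not sweep.crosses_half_pi():
        raise ExtractionError(
            f"phase at gap {sweep.gap_height * 1e9:.0f} nm never crosses pi/2"
        )
    mask = np.abs(sweep.phases - HALF_PI) <= window_halfwidth
    if mask.sum() < 4:
        raise InsufficientDataError(
            f"only {int(mask.sum())} samples within {window_halfwidth} rad of pi/2 "
            f"at gap {sweep.gap_height * 1e9:.0f} nm (need >= 4)"
        )
    freqs = sweep.frequencies[mask]
    phases = sweep.phases[mask]
    poly = Polynomial.fit(freqs, phases - HALF_PI, deg=2)
    roots = poly.roots()
    real_roots = roots[np.isclose(roots.imag, 0.0, atol=1e-6)].real
    if len(real_roots) == 0:
        raise ExtractionError(
            f"quadratic phase fit has no real pi/2 crossing at gap "
            f"{sweep.gap_height * 1e9:.0f} nm"
        )
    anchor = sweep.frequencies[np.argmin(np.abs(sweep.phases - HALF_PI))]
    f_pi2 = float(real_roots[np.argmin(np.abs(real_roots - anchor))])
    if not sweep.frequencies[0] <= f_pi2 <= sweep.frequencies[-1]:
        raise ExtractionError(
            f"fitted pi/2 crossing {f_pi2:.1f} Hz lies outside the sweep range "
            f"at gap {sweep.gap_height * 1e9:.0f} nm"
        )
    logger.info(
        "f_pi/2 at gap %.0f nm: %.2f Hz (%d samples in window)",
        sweep.gap_height * 1e9,
        f_pi2,
        int(mask.sum()),
    )
    return f_pi2


def select_resonance_peak(
    sweep: FrequencySweep, expected_f0: float, search_window: float
) -> float:
    """Frequency of the largest amplitude peak near the expected resonance.

    Piezo excitation in liquid produces a forest of spurious peaks; the
    cantilever resonance is taken as the largest local amplitude maximum
    within ``expected_f0 +/- search_window``, ties broken toward
    ``expected_f0``.
    """
    if sweep.amplitudes is None:
        raise ExtractionError("sweep carries no amplitude data")
    in_window = np.abs(sweep.frequencies - expected_f0) <= search_window
    if in_window.sum() < 3:
        raise PeakNotFoundError("fewer than 3 amplitude samples in the search window")
    amp = sweep.amplitudes
    # local maxima over the full record, then restricted to the window
    interior = np.arange(1, len(amp) - 1)
    is_peak = (amp[interior] >= amp[interior - 1]) & (amp[interior] >= amp[interior + 1])
    peak_idx = interior[is_peak]
    peak_idx = peak_idx[in_window[peak_idx]]
    if len(peak_idx) == 0:
        raise PeakNotFoundError(
            f"no local amplitude maximum within {search_window:.0f} Hz of "
            f"{expected_f0:.0f} Hz"
        )
    peak_amps = amp[peak_idx]
    best = peak_amps.max()
    candidates = peak_idx[peak_amps >= best * (1 - 1e-12)]
    chosen = candidates[np.argmin(np.abs(sweep.frequencies[candidates] - expected_f0))]
    return float(sweep.frequencies[chosen])


def build_shift_gap_curve(
    series: SweepSeries,
    window_halfwidth: float = DEFAULT_PI2_WINDOW,
    monotonicity_tolerance: float = 5.0,
) -> ShiftGapCurve:
    """Reconstruct the frequency-shift-versus-gap curve for a series.

    Shifts are ``f_pi/2(h) - f_pi/2(h_far)``; the reference gap has zero
    shift by construction.  Hydrodynamics make the shift non-increasing in
    gap; violations beyond ``monotonicity_tolerance`` (Hz) raise a warning
    but never an error — the tension fit is the arbiter of noisy data.
    """
    f_per_gap: dict[float, float] = {}
    for sweep in series.sweeps:
        try:
            f_per_gap[sweep.gap_height] = extract_f_pi2(sweep, window_halfwidth)
        except ExtractionError as exc:
            raise ExtractionError(
                f"extraction failed at gap {sweep.gap_height * 1e9:.0f} nm: {exc}"
            ) from exc
    f_far = f_per_gap[series.reference_sweep.gap_height]
    gaps = series.gaps
    shifts = np.array([f_per_gap[h] - f_far for h in gaps])
    shifts[np.isclose(gaps, series.reference_gap, rtol=1e-12)] = 0.0

    # gaps are sorted descending, so shifts should be non-decreasing
    drops = np.diff(shifts)
    if np.any(drops < -monotonicity_tolerance):
        warnings.warn(
            "frequency shift is not monotone in gap beyond the noise tolerance; "
            "check sweep quality",
            stacklevel=2,
        )
    return ShiftGapCurve(gaps=gaps, shifts=shifts, f_far=f_far, h_far=series.reference_gap)


def phase_slope(
    series: SweepSeries,
    at_gap: float = DEFAULT_SLOPE_GAP,
    window_halfwidth: float = DEFAULT_SLOPE_WINDOW,
) -> PhaseSlope:
    """Slope dphi/df of the phase-frequency curve at its pi/2 crossing.

    A third-order polynomial is fitted to the samples with
    ``|phase - pi/2| <= window_halfwidth`` of the sweep recorded at
    ``at_gap`` (nearest gap with a warning if absent) and differentiated at
    f_pi/2 of that sweep.
    """
    sweep = series.sweep_at(at_gap)
    if sweep is None:
        gaps = series.gaps
        nearest = gaps[np.argmin(np.abs(gaps - at_gap))]
        warnings.warn(
            f"no sweep at {at_gap * 1e9:.0f} nm; using nearest gap "
            f"{nearest * 1e9:.0f} nm",
            stacklevel=2,
        )
        sweep = series.sweep_at(nearest)
        assert sweep is not None
    mask = np.abs(sweep.phases - HALF_PI) <= window_halfwidth
    if mask.sum() < 5:
        raise InsufficientDataError(
            f"only {int(mask.sum())} samples within {window_halfwidth} rad of pi/2 "
            f"at gap {sweep.gap_height * 1e9:.0f} nm (need >= 5 for the cubic fit)"
        )
    freqs = sweep.frequencies[mask]
    poly = Polynomial.fit(freqs, sweep.phases[mask], deg=3)
    f_pi2 = extract_f_pi2(sweep)
    slope = float(poly.deriv()(f_pi2))
    logger.info(
        "dphi/df at gap %.0f nm: %.4g rad/Hz", sweep.gap_height * 1e9, slope
    )
    return PhaseSlope(
        slope=slope,
        evaluation_gap=sweep.gap_height,
        fit_window=(float(freqs[0]), float(freqs[-1])),
    )
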