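"""pi/2-resonance extraction, shift-gap reconstruction, and phase slope."""

import numpy as np
import pytest

from epimech import (
    FrequencySweep,
    SimulationConfig,
    SweepSeries,
    build_shift_gap_curve,
    extract_f_pi2,
    phase_slope,
    predict_frequency_shift,
    select_resonance_peak,
)
from epimech.errors import ExtractionError, InsufficientDataError, PeakNotFoundError
from epimech.synthetic import _sho_phase, simulate_sweep_series

HALF_PI = np.pi / 2


def _sweep(freqs, phases, gap=2e-6, amplitudes=None):
    return FrequencySweep(
        gap_height=gap, frequencies=freqs, phases=phases, amplitudes=amplitudes
    )


class TestExtractFPi2:
    def test_linear_phase_is_exact(self):
        f = np.linspace(30000, 40000, 201)
        sweep = _sweep(f, HALF_PI - 1e-4 * (f - 35000))
        assert extract_f_pi2(sweep) == pytest.approx(35000.0, rel=1e-9)

    def test_quadratic_phase_recovers_analytic_root(self):
        # phase = pi/2 + a (f-f0) + b (f-f0)^2 with a root constructed at 36250
        f = np.linspace(34000, 38000, 301)
        a, b, root = -2e-4, 1.5e-9, 36250.0
        # choose c so that the quadratic vanishes exactly at the root
        x = f - root
        phases = HALF_PI + x * (a + b * x)
        sweep = _sweep(f, phases)
        assert extract_f_pi2(sweep) == pytest.approx(root, abs=1e-6)

    def test_sho_phase_with_noise_recovers_f0(self):
        # Monte-Carlo contract: 95% of replicates within 0.2% of f0
        f0, q, n = 35000.0, 3.0, 200
        f = np.linspace(f0 - 5000, f0 + 5000, n)
        clean = _sho_phase(f, f0, q)
        hits = 0
        reps = 500
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            sweep = _sweep(f, clean + 0.01 * rng.standard_normal(n))
            if abs(extract_f_pi2(sweep) - f0) / f0 < 0.002:
                hits += 1
        assert hits / reps >= 0.95

    def test_no_crossing_fails_loudly(self):
        f = np.linspace(30000, 40000, 50)
        with pytest.raises(ExtractionError, match="pi/2"):
            extract_f_pi2(_sweep(f, np.full(50, 2.5)))

    def test_too_few_points_in_window(self):
        f = np.linspace(30000, 40000, 6)
        phases = HALF_PI - 1e-3 * (f - 35000)  # steep: few samples near pi/2
        with pytest.raises(InsufficientDataError):
            extract_f_pi2(_sweep(f, phases), window_halfwidth=0.05)


class TestSelectResonancePeak:
    def _two_peak_sweep(self):
        f = np.linspace(26000, 40000, 701)
        amp = (
            1.0 / (1 + ((f - 34000) / 300) ** 2)
            + 0.6 / (1 + ((f - 36500) / 300) ** 2)
            + 1.4 / (1 + ((f - 28000) / 300) ** 2)
        )
        phases = _sho_phase(f, 34000, 3.0)
        return _sweep(f, phases, amplitudes=amp)

    def test_single_peak(self):
        f = np.linspace(32000, 38000, 601)
        amp = 1.0 / (1 + ((f - 35000) / 400) ** 2)
        sweep = _sweep(f, _sho_phase(f, 35000, 3.0), amplitudes=amp)
        assert select_resonance_peak(sweep, 35000, 3000) == pytest.approx(35000, abs=20)

    def test_largest_in_window_wins(self):
        sweep = self._two_peak_sweep()
        assert select_resonance_peak(sweep, 35000, 3000) == pytest.approx(34000, abs=30)

    def test_spurious_peak_outside_window_ignored(self):
        # the 28 kHz peak is the global maximum but lies outside the window
        sweep = self._two_peak_sweep()
        chosen = select_resonance_peak(sweep, 35000, 3000)
        assert abs(chosen - 28000) > 1000

    def test_no_peak_in_window(self):
        f = np.linspace(32000, 38000, 100)
        sweep = _sweep(f, _sho_phase(f, 35000, 3.0), amplitudes=np.linspace(1, 2, 100))
        with pytest.raises(PeakNotFoundError):
            select_resonance_peak(sweep, 35000, 500)


class TestShiftGapCurve:
    def test_forward_model_round_trip(self, calib):
        series = simulate_sweep_series(
            SimulationConfig(calibration=calib, tension=2.2e-3, seed=0)
        )
        curve = build_shift_gap_curve(series)
        predicted = predict_frequency_shift(calib, 2.2e-3, curve.gaps, curve.h_far)
        np.testing.assert_allclose(curve.shifts, predicted, rtol=5e-3, atol=0.5)

    def test_identical_sweeps_give_zero_shifts(self, calib):
        f = np.linspace(30000, 40000, 201)
        phases = _sho_phase(f, 35000, 3.0)
        sweeps = [
            FrequencySweep(gap_height=g, frequencies=f.copy(), phases=phases.copy())
            for g in (6e-6, 4e-6, 2e-6)
        ]
        series = SweepSeries(calibration=calib, sweeps=sweeps, reference_gap=6e-6)
        curve = build_shift_gap_curve(series)
        np.testing.assert_allclose(curve.shifts, 0.0, atol=1e-6)

    def test_shifts_positive_and_decreasing_in_gap(self, control_series):
        curve = build_shift_gap_curve(control_series)
        assert curve.shifts[0] == 0.0  # reference gap first (gaps descending)
        assert np.all(curve.shifts[1:] > 0)
        assert np.all(np.diff(curve.shifts) > 0)  # shift grows as gap shrinks

    def test_frequency_translation_invariance(self, calib, control_series):
        curve = build_shift_gap_curve(control_series)
        shifted_sweeps = [
            FrequencySweep(
                gap_height=s.gap_height,
                frequencies=s.frequencies + 1234.5,
                phases=s.phases.copy(),
            )
            for s in control_series.sweeps
        ]
        shifted = SweepSeries(
            calibration=calib, sweeps=shifted_sweeps, reference_gap=6e-6
        )
        curve2 = build_shift_gap_curve(shifted)
        np.testing.assert_allclose(curve2.shifts, curve.shifts, atol=1e-6)


class TestPhaseSlope:
    def test_linear_phase_slope_exact(self, calib):
        f = np.linspace(30000, 40000, 201)
        sweep = FrequencySweep(
            gap_height=2e-6, frequencies=f, phases=HALF_PI - 1e-4 * (f - 35000)
        )
        series = SweepSeries(calibration=calib, sweeps=[sweep], reference_gap=2e-6)
        result = phase_slope(series, at_gap=2e-6)
        assert result.slope == pytest.approx(-1e-4, rel=1e-9)

    def test_sho_slope_matches_closed_form(self, calib):
        # at resonance the damped-oscillator slope is -2Q/f0
        f0, q = 35000.0, 3.0
        f = np.linspace(f0 - 5000, f0 + 5000, 401)
        sweep = FrequencySweep(gap_height=2e-6, frequencies=f, phases=_sho_phase(f, f0, q))
        series = SweepSeries(calibration=calib, sweeps=[sweep], reference_gap=2e-6)
        result = phase_slope(series, at_gap=2e-6)
        assert result.slope == pytest.approx(-2 * q / f0, rel=0.01)

    def test_slope_stable_across_gaps(self, calib):
        # constant-Q series: slope estimates at 1.5/2.0/2.5 um agree within 2%
        config = SimulationConfig(
            calibration=calib, viscosity_eff=None, quality_factor=3.0, seed=0
        )
        series = simulate_sweep_series(config)
        slopes = [phase_slope(series, at_gap=g).slope for g in (1.5e-6, 2.0e-6, 2.5e-6)]
        assert max(slopes) / min(slopes) == pytest.approx(1.0, abs=0.02)

    def test_constant_phase_offset_invariance(self, calib):
        # dphi/df is a derivative, so a constant offset leaves it unchanged;
        # only the pi/2 evaluation point moves, a second-order effect because
        # the slope is extremal at resonance
        f0, q = 35000.0, 5.0
        f = np.linspace(f0 - 5000, f0 + 5000, 401)
        base = _sho_phase(f, f0, q)
        slopes = []
        for offset in (0.0, 0.02):
            sweep = FrequencySweep(gap_height=2e-6, frequencies=f, phases=base + offset)
            series = SweepSeries(calibration=calib, sweeps=[sweep], reference_gap=2e-6)
            slopes.append(phase_slope(series, at_gap=2e-6).slope)
        assert slopes[1] == pytest.approx(slopes[0], rel=5e-3)

    def test_nearest_gap_fallback_warns(self, control_series):
        with pytest.warns(UserWarning, match="nearest"):
            result = phase_slope(control_series, at_gap=2.2e-6)
        assert result.evaluation_gap == pytest.approx(2.0e-6)
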