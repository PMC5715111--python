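"""Forward squeeze-film model and tension recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epimech import (
    ShiftGapCurve,
    SimulationConfig,
    build_shift_gap_curve,
    effective_probe_diameter,
    fit_tension,
    initial_tension_estimate,
    predict_frequency_shift,
)
from epimech.errors import DegenerateDataError, DomainError, ValidationError
from epimech.synthetic import simulate_sweep_series

GAPS_12 = np.arange(6.0e-6, 0.4e-6, -0.5e-6)


def _forward_curve(calib, tension, gaps=GAPS_12, h_far=6e-6):
    shifts = predict_frequency_shift(calib, tension, gaps, h_far)
    return ShiftGapCurve(gaps=gaps, shifts=shifts, f_far=calib.f_far, h_far=h_far)


class TestForwardModel:
    def test_reference_shift_at_one_micron(self, calib):
        # independently hand-evaluated value for the standard probe at T = 2.2 nN/um
        shift = predict_frequency_shift(calib, 2.2e-3, 1.0e-6, 6.0e-6)
        assert shift == pytest.approx(844.8, abs=0.05)

    def test_zero_at_reference_gap(self, calib):
        assert predict_frequency_shift(calib, 2.2e-3, 6.0e-6, 6.0e-6) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_gap_scaling(self, calib):
        # doubling h multiplies the shift by sqrt(2) * (h_far/2h - 1)/(h_far/h - 1)
        s1 = predict_frequency_shift(calib, 2.2e-3, 1.0e-6, 6.0e-6)
        s2 = predict_frequency_shift(calib, 2.2e-3, 2.0e-6, 6.0e-6)
        assert s2 == pytest.approx(477.9, abs=0.05)
        assert s2 == pytest.approx(s1 * np.sqrt(2) * 2 / 5, rel=1e-12)

    def test_rejects_nonpositive_inputs(self, calib):
        with pytest.raises(DomainError):
            predict_frequency_shift(calib, -1e-3, 1e-6, 6e-6)
        with pytest.raises(DomainError):
            predict_frequency_shift(calib, 2.2e-3, 7e-6, 6e-6)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=1e-5, max_value=1e-2))
    def test_power_law_in_tension(self, tension):
        # shift scales as T^(3/2) over three decades
        from epimech import CantileverCalibration

        calib = CantileverCalibration(1.0, 12.5e-6, 0.7e-3, f_far=35e3)
        base = predict_frequency_shift(calib, tension, 1e-6, 6e-6)
        doubled = predict_frequency_shift(calib, 2 * tension, 1e-6, 6e-6)
        assert doubled / base == pytest.approx(2**1.5, rel=1e-9)


class TestInitialEstimate:
    def test_inverts_forward_example(self, calib):
        t = initial_tension_estimate(calib, 844.7696784384771, 1.0e-6, 6.0e-6)
        assert t == pytest.approx(2.2e-3, rel=1e-9)

    def test_consistency_across_gaps(self, calib):
        for h in (0.5e-6, 1e-6, 2e-6, 4e-6):
            shift = float(predict_frequency_shift(calib, 2.2e-3, h, 6e-6))
            assert initial_tension_estimate(calib, shift, h, 6e-6) == pytest.approx(
                2.2e-3, rel=1e-9
            )

    def test_shift_doubling_scales_two_thirds(self, calib):
        t1 = initial_tension_estimate(calib, 400.0, 1e-6, 6e-6)
        t2 = initial_tension_estimate(calib, 800.0, 1e-6, 6e-6)
        assert t2 / t1 == pytest.approx(2 ** (2 / 3), rel=1e-12)

    def test_round_trip_reproduces_shift(self, calib):
        t = initial_tension_estimate(calib, 613.7, 1.5e-6, 6e-6)
        assert predict_frequency_shift(calib, t, 1.5e-6, 6e-6) == pytest.approx(
            613.7, rel=1e-9
        )

    def test_rejects_nonpositive_shift(self, calib):
        with pytest.raises(DomainError):
            initial_tension_estimate(calib, 0.0, 1e-6, 6e-6)


class TestEffectiveProbeDiameter:
    def test_reference_value(self):
        assert effective_probe_diameter(12.5e-6, 0.5e-6) == pytest.approx(10e-6, rel=1e-12)

    def test_square_root_scaling(self):
        assert effective_probe_diameter(12.5e-6, 2e-6) == pytest.approx(
            2 * effective_probe_diameter(12.5e-6, 0.5e-6), rel=1e-12
        )

    def test_rejects_zero_gap(self):
        with pytest.raises(DomainError):
            effective_probe_diameter(12.5e-6, 0.0)


class TestFitTension:
    @pytest.mark.parametrize("t_true", [1.4e-3, 2.2e-3, 4.8e-3])
    def test_noiseless_forward_round_trip(self, calib, t_true):
        fit = fit_tension(_forward_curve(calib, t_true), calib)
        assert fit.tension == pytest.approx(t_true, rel=1e-6)

    def test_noisy_recovery_bias_below_one_percent(self, calib):
        t_true = 4.8e-3
        clean = _forward_curve(calib, t_true)
        rng = np.random.default_rng(2024)
        estimates = []
        for _ in range(200):
            noise = 5.0 * rng.standard_normal(len(clean.gaps))
            noise[np.isclose(clean.gaps, clean.h_far)] = 0.0
            noisy = ShiftGapCurve(
                gaps=clean.gaps,
                shifts=clean.shifts + noise,
                f_far=clean.f_far,
                h_far=clean.h_far,
            )
            estimates.append(fit_tension(noisy, calib).tension)
        assert np.mean(estimates) == pytest.approx(t_true, rel=0.01)

    def test_reported_standard_error_matches_spread(self, calib):
        t_true = 4.8e-3
        clean = _forward_curve(calib, t_true)
        rng = np.random.default_rng(7)
        estimates, ses = [], []
        for _ in range(200):
            noise = 5.0 * rng.standard_normal(len(clean.gaps))
            noise[np.isclose(clean.gaps, clean.h_far)] = 0.0
            noisy = ShiftGapCurve(
                gaps=clean.gaps,
                shifts=clean.shifts + noise,
                f_far=clean.f_far,
                h_far=clean.h_far,
            )
            fit = fit_tension(noisy, calib)
            estimates.append(fit.tension)
            ses.append(fit.standard_error)
        assert np.mean(ses) == pytest.approx(np.std(estimates), rel=0.25)

    def test_gap_subset_stability(self, calib):
        curve = _forward_curve(calib, 2.2e-3)
        full = fit_tension(curve, calib).tension
        for lo, hi in [(0.5e-6, 2e-6), (2e-6, 6e-6), (1e-6, 3e-6)]:
            sub = fit_tension(curve, calib, min_gap=lo, max_gap=hi).tension
            assert sub == pytest.approx(full, rel=1e-6)

    def test_grid_search_oracle(self, calib):
        # exhaustive 1-D golden-section refinement over T agrees with the fit
        rng = np.random.default_rng(99)
        for _ in range(20):
            t_true = 10 ** rng.uniform(-3.3, -2.2)
            clean = _forward_curve(calib, t_true)
            noise = 5.0 * rng.standard_normal(len(clean.gaps))
            noise[np.isclose(clean.gaps, clean.h_far)] = 0.0
            curve = ShiftGapCurve(
                gaps=clean.gaps,
                shifts=clean.shifts + noise,
                f_far=clean.f_far,
                h_far=clean.h_far,
            )

            def rss(t):
                pred = predict_frequency_shift(calib, t, curve.gaps, curve.h_far)
                return float(np.sum((curve.shifts - pred) ** 2))

            from scipy.optimize import minimize_scalar

            oracle = minimize_scalar(
                rss, bounds=(t_true / 10, t_true * 10), method="bounded",
                options={"xatol": 1e-12},
            ).x
            fit = fit_tension(curve, calib)
            assert fit.tension == pytest.approx(oracle, rel=1e-3)

    def test_bead_size_robustness(self, calib):
        # 20/25/35 um beads at fixed tension give the same estimate
        import dataclasses

        recovered = []
        for radius in (10e-6, 12.5e-6, 17.5e-6):
            c = dataclasses.replace(calib, bead_radius=radius)
            series = simulate_sweep_series(
                SimulationConfig(calibration=c, tension=2.2e-3, seed=0)
            )
            curve = build_shift_gap_curve(series)
            recovered.append(fit_tension(curve, c).tension)
        assert max(recovered) / min(recovered) == pytest.approx(1.0, abs=0.01)

    def test_all_zero_shifts_is_degenerate(self, calib):
        curve = ShiftGapCurve(
            gaps=GAPS_12, shifts=np.zeros(len(GAPS_12)), f_far=35e3, h_far=6e-6
        )
        with pytest.raises(DegenerateDataError):
            fit_tension(curve, calib)

    def test_too_few_points_rejected(self, calib):
        curve = _forward_curve(calib, 2.2e-3)
        with pytest.raises(ValidationError):
            fit_tension(curve, calib, min_gap=5.4e-6, max_gap=6e-6)

    def test_offset_cofit_recovers_zero_offset(self, calib):
        curve = _forward_curve(calib, 2.2e-3)
        fit = fit_tension(curve, calib, fit_offset=True)
        assert fit.gap_offset == pytest.approx(0.0, abs=2e-9)
        assert fit.tension == pytest.approx(2.2e-3, rel=1e-4)

    def test_result_diameters_match_gaps(self, calib):
        fit = fit_tension(_forward_curve(calib, 2.2e-3), calib)
        assert fit.n_points == len(GAPS_12)
        np.testing.assert_allclose(
            fit.effective_probe_diameters,
            effective_probe_diameter(calib.bead_radius, GAPS_12),
            rtol=1e-12,
        )
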