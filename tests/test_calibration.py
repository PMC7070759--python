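"""Calibration fitters: plateau averaging, power-law/linear fits, diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitsole.calibration import (
    FsrCalibration,
    StaircaseRecording,
    detect_press_events,
    extract_plateau_means,
    fit_fsr_power_law,
    fit_piezo_line,
    fsr_weight,
    fsr_resistance_for_weight,
    hysteresis_error,
    mems_repeatability,
    staircase_points,
)
from gaitsole.insole_sim import (
    MemsSensorModel,
    simulate_mems_trials,
    simulate_staircase,
)

TRIAL1 = FsrCalibration(coefficient_a=5035.2, exponent_b=-1.72)


def make_staircase(levels, step_s=4.0, fs=10.0, voltage_fn=None):
    w = np.repeat(np.asarray(levels, dtype=float), int(step_s * fs))
    t = np.arange(w.size) / fs
    v = voltage_fn(w) if voltage_fn else np.full(w.size, 1.0)
    return StaircaseRecording(time=t, reference_weight=w, sensor_voltage=v)


class TestPlateauExtraction:
    def test_ideal_loading_staircase_has_11_plateaus(self):
        rec = make_staircase(np.arange(0.0, 5001.0, 500.0))
        plateaus = extract_plateau_means(rec, settle_time=1.0)
        assert [p[0] for p in plateaus] == pytest.approx(list(np.arange(0, 5001, 500)))

    def test_constant_recording_is_one_plateau(self):
        rec = make_staircase([1000.0])
        (plateau,) = extract_plateau_means(rec, settle_time=1.0)
        assert plateau[0] == pytest.approx(1000.0)

    def test_noise_free_means_equal_generating_values(self):
        rec = make_staircase([500.0, 1000.0], voltage_fn=lambda w: w * 1e-3)
        plateaus = extract_plateau_means(rec, settle_time=1.0)
        for weight, volts, _ in plateaus:
            assert volts == pytest.approx(weight * 1e-3)

    def test_settle_longer_than_plateau_is_an_error(self):
        rec = make_staircase([0.0, 500.0, 1000.0], step_s=0.5)
        with pytest.raises(ValueError):
            extract_plateau_means(rec, settle_time=2.0)


class TestPowerLawFit:
    def test_recovers_trial1_model_from_clean_points(self):
        r = np.logspace(0, 1.2, 10)
        pts = list(zip(TRIAL1.coefficient_a * r**TRIAL1.exponent_b, r))
        cal = fit_fsr_power_law(pts)
        assert cal.coefficient_a == pytest.approx(5035.2, rel=1e-6)
        assert cal.exponent_b == pytest.approx(-1.72, rel=1e-6)
        assert cal.fit_r2 == pytest.approx(1.0)

    def test_identity_law(self):
        r = np.array([1.0, 2.0, 5.0])
        cal = fit_fsr_power_law(list(zip(r, r)))
        assert cal.coefficient_a == pytest.approx(1.0)
        assert cal.exponent_b == pytest.approx(1.0)

    def test_matches_grid_search_oracle(self):
        """Log-space least squares equals brute-force grid minimization."""
        rng = np.random.default_rng(7)
        r = np.array([0.8, 1.5, 3.0, 6.0, 12.0])
        w = 4000.0 * r**-1.8 * np.exp(rng.normal(0, 0.05, r.size))
        cal = fit_fsr_power_law(list(zip(w, r)))

        log_a_grid = np.linspace(np.log(2000), np.log(8000), 401)
        b_grid = np.linspace(-2.5, -1.2, 401)
        best = (np.inf, None, None)
        for la in log_a_grid:
            resid = np.log(w)[None, :] - (la + b_grid[:, None] * np.log(r)[None, :])
            sse = (resid**2).sum(axis=1)
            i = int(np.argmin(sse))
            if sse[i] < best[0]:
                best = (sse[i], la, b_grid[i])
        assert np.log(cal.coefficient_a) == pytest.approx(
            best[1], abs=np.diff(log_a_grid)[0]
        )
        assert cal.exponent_b == pytest.approx(best[2], abs=np.diff(b_grid)[0])

    def test_rejects_nonpositive_and_tiny_sets(self):
        with pytest.raises(ValueError):
            fit_fsr_power_law([(100.0, 1.0), (50.0, 2.0)])
        with pytest.raises(ValueError):
            fit_fsr_power_law([(100.0, 1.0), (0.0, 2.0), (50.0, 3.0)])


class TestFsrWeight:
    def test_printed_model_at_1_kohm(self):
        assert fsr_weight(1.0, TRIAL1) == pytest.approx(5035.2)

    def test_vanishes_at_open_circuit(self):
        assert fsr_weight(np.inf, TRIAL1) == 0.0

    def test_round_trip_with_resistance_inverse(self):
        for w in (250.0, 1000.0, 5000.0):
            assert fsr_weight(fsr_resistance_for_weight(w, TRIAL1), TRIAL1) == pytest.approx(w)

    def test_monotone_decreasing(self):
        r = np.logspace(-0.5, 1.5, 50)
        w = fsr_weight(r, TRIAL1)
        assert np.all(np.diff(w) < 0)

    def test_rejects_nonpositive_resistance(self):
        with pytest.raises(ValueError):
            fsr_weight(0.0, TRIAL1)


class TestHysteresisError:
    def test_identical_fits_give_zero(self):
        assert hysteresis_error(TRIAL1, TRIAL1) == 0.0

    def test_doubled_coefficient_gives_half(self):
        doubled = FsrCalibration(2 * TRIAL1.coefficient_a, TRIAL1.exponent_b)
        assert hysteresis_error(TRIAL1, doubled) == pytest.approx(0.5)

    @settings(deadline=None, max_examples=25)
    @given(
        b0=st.floats(-3.0, -1.0),
        d1=st.floats(0.01, 0.4),
        d2=st.floats(0.01, 0.4),
    )
    def test_monotone_in_exponent_gap(self, b0, d1, d2):
        lo, hi = sorted((d1, d2))
        base = FsrCalibration(5000.0, b0)
        near = FsrCalibration(5000.0, b0 - lo)
        far = FsrCalibration(5000.0, b0 - hi)
        assert hysteresis_error(base, far) >= hysteresis_error(base, near) - 1e-12


class TestPressEvents:
    def test_flat_signal_has_no_events(self):
        t = np.arange(0, 10, 0.001)
        assert detect_press_events(t, np.zeros_like(t), np.zeros_like(t)) == []

    def test_five_impulses_paired_with_weight_bumps(self):
        fs = 1000.0
        t = np.arange(0, 12, 1 / fs)
        piezo = np.zeros_like(t)
        ref = np.zeros_like(t)
        amps = [1.0, 2.0, 3.0, 4.0, 5.0]
        for k, a in enumerate(amps):
            i = int((k + 1) * 2 * fs)
            piezo[i] = a
            ref[i - 20] = 300.0 * a
        events = detect_press_events(t, piezo, ref)
        assert [e.piezo_peak for e in events] == pytest.approx(amps)
        assert [e.reference_peak for e in events] == pytest.approx([300.0 * a for a in amps])

    def test_close_pair_keeps_the_larger(self):
        t = np.arange(0, 4, 0.001)
        piezo = np.zeros_like(t)
        piezo[1000] = 1.0
        piezo[1200] = 2.0  # 0.2 s later, inside the 0.5 s window
        events = detect_press_events(t, piezo, np.zeros_like(t))
        assert len(events) == 1
        assert events[0].piezo_peak == pytest.approx(2.0)


class TestPiezoLineFit:
    def test_recovers_printed_trial1_line(self):
        from gaitsole.calibration import PressEvent

        m, c = 0.42867, -0.19123
        v = np.linspace(2.0, 10.0, 6)
        events = [
            PressEvent(time=i, piezo_peak=vi, reference_peak=(m * vi + c) * 1000.0)
            for i, vi in enumerate(v)
        ]
        cal = fit_piezo_line(events)
        assert cal.slope_m == pytest.approx(m, rel=1e-9)
        assert cal.intercept_c == pytest.approx(c, rel=1e-9)

    def test_identity_line(self):
        from gaitsole.calibration import PressEvent

        events = [PressEvent(i, float(i + 1), (i + 1) * 1000.0) for i in range(4)]
        cal = fit_piezo_line(events)
        assert cal.slope_m == pytest.approx(1.0)
        assert cal.intercept_c == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_on_three_points(self):
        from gaitsole.calibration import PressEvent

        v = np.array([1.0, 2.0, 4.0])
        w_kg = np.array([0.5, 0.8, 1.9])
        events = [PressEvent(i, vi, wi * 1000.0) for i, (vi, wi) in enumerate(zip(v, w_kg))]
        cal = fit_piezo_line(events)
        # hand-formed normal equations
        n = v.size
        m = (n * np.sum(v * w_kg) - v.sum() * w_kg.sum()) / (n * np.sum(v**2) - v.sum() ** 2)
        c = (w_kg.sum() - m * v.sum()) / n
        assert cal.slope_m == pytest.approx(m, rel=1e-12)
        assert cal.intercept_c == pytest.approx(c, rel=1e-12)

    def test_identical_peaks_rejected(self):
        from gaitsole.calibration import PressEvent

        events = [PressEvent(i, 2.0, 500.0) for i in range(3)]
        with pytest.raises(ValueError):
            fit_piezo_line(events)


class TestMemsRepeatability:
    def test_consistent_trials_not_flagged(self):
        trials = [[(v, 1.4 * v + 0.1) for v in (1.0, 2.0, 3.0)] for _ in range(3)]
        report = mems_repeatability(trials)
        assert not report.flagged
        assert report.sign_consistency == 1.0

    def test_mixed_slope_signs_flagged(self):
        up = [(v, 1.5 * v) for v in (1.0, 2.0, 3.0)]
        down = [(v, -1.2 * v) for v in (1.0, 2.0, 3.0)]
        report = mems_repeatability([up, down, up])
        assert report.flagged
        assert "sign" in report.reason

    def test_bench_trial_slope_spread_triggers_cv_flag(self):
        # three same-sign slope estimates whose spread is beyond the limit
        trials = [
            [(v, m * v) for v in (1.0, 2.0, 3.0)] for m in (1.4145, 1.5215, 0.80343)
        ]
        report = mems_repeatability(trials)
        assert report.flagged
        assert report.slope_cv > 0.30

    def test_3axis_simulation_random_orientations_flagged_z_only_not(self, rng):
        model = MemsSensorModel(axis_gains=(1.0, 1.0, 1.0))
        random_trials = simulate_mems_trials(model, orientation_mode="random", rng=rng)
        z_trials = simulate_mems_trials(
            model, orientation_mode="z", rng=np.random.default_rng(5)
        )
        assert mems_repeatability(random_trials).flagged
        assert not mems_repeatability(z_trials).flagged


class TestStaircaseToFitPipeline:
    def test_noise_free_round_trip_recovers_generator(self, ideal_fsr_model, rig):
        rec = simulate_staircase(ideal_fsr_model, rig.divider)
        for phase in ("loading", "offloading"):
            cal = fit_fsr_power_law(
                staircase_points(rec, rig.divider, phase=phase), phase=phase
            )
            assert cal.coefficient_a == pytest.approx(5035.2, rel=1e-6)
            assert cal.exponent_b == pytest.approx(-1.72, rel=1e-6)

    def test_noisy_recovery_within_5pct_over_20_seeds(self, rig):
        from gaitsole.insole_sim import FsrSensorModel

        model = FsrSensorModel(voltage_noise_sd=0.005, hysteresis_factor=0.0)
        for seed in range(20):
            rec = simulate_staircase(
                model, rig.divider, rng=np.random.default_rng(seed)
            )
            cal = fit_fsr_power_law(
                staircase_points(rec, rig.divider, phase="offloading")
            )
            assert cal.coefficient_a == pytest.approx(5035.2, rel=0.05)
            assert cal.exponent_b == pytest.approx(-1.72, rel=0.05)

    def test_hysteresis_separates_branches(self, rig):
        from dataclasses import replace

        from gaitsole.insole_sim import FsrSensorModel

        model = FsrSensorModel(hysteresis_factor=0.05, voltage_noise_sd=0.0)
        rec = simulate_staircase(model, rig.divider)
        loading = fit_fsr_power_law(
            staircase_points(rec, rig.divider, phase="loading"), phase="loading"
        )
        offloading = fit_fsr_power_law(
            staircase_points(rec, rig.divider, phase="offloading"), phase="offloading"
        )
        assert hysteresis_error(loading, offloading) > 0.01
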