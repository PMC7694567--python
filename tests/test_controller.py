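"""Proportional resistance controller: stance detection, moment estimation,
calibration, torque law and full-session behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exoresist import (
    CalibrationResult,
    ControllerConfig,
    ProportionalResistanceController,
    calibrate_peak_moment,
    compute_resistance_torque,
    detect_stance,
    estimate_ankle_moment,
    generate_gait_trial,
    run_session,
)
from exoresist.errors import CalibrationError, ConfigurationError, ValidationError


class TestDetectStance:
    def test_all_zero_force_has_no_stance(self):
        stance, intervals = detect_stance(np.zeros(100), 10.0)
        assert not stance.any()
        assert intervals == []

    def test_square_wave_intervals_are_the_high_runs(self):
        force = np.tile(np.r_[np.zeros(50), np.full(50, 100.0)], 3)
        stance, intervals = detect_stance(force, 10.0)
        assert intervals == [(50, 100), (150, 200), (250, 300)]
        assert np.array_equal(stance, force > 10.0)

    def test_stride_count_matches_cadence(self, profile):
        # 60 s at 100 steps/min -> 50 strides per limb
        trial = generate_gait_trial(
            profile, duration=60, cadence=100, seed=21
        )
        for limb in trial.limbs:
            _, intervals = detect_stance(
                trial.forefoot_force[limb], 20.0,
                sample_rate=trial.sample_rate, min_duration_s=0.1,
            )
            assert abs(len(intervals) - 50) <= 1

    def test_debounce_drops_short_chatter(self):
        force = np.zeros(200)
        force[10:12] = 100.0  # 2 samples at 100 Hz = 20 ms of chatter
        force[50:150] = 100.0
        _, intervals = detect_stance(force, 10.0, sample_rate=100, min_duration_s=0.1)
        assert intervals == [(50, 150)]

    def test_empty_series_rejected(self):
        with pytest.raises(ValidationError):
            detect_stance(np.array([]), 10.0)


class TestEstimateMoment:
    @pytest.mark.parametrize(
        "force,lever,expected", [(0.0, 0.15, 0.0), (100.0, 0.15, 15.0)]
    )
    def test_lever_arm_arithmetic(self, force, lever, expected):
        assert estimate_ankle_moment(force, lever) == pytest.approx(expected)

    def test_negative_force_rejected(self):
        with pytest.raises(ValidationError):
            estimate_ankle_moment(-1.0, 0.15)
        with pytest.raises(ValidationError):
            estimate_ankle_moment(1.0, 0.0)

    def test_peak_timing_coherent_with_ground_truth(self, profile):
        trial = generate_gait_trial(profile, duration=30, seed=8)
        lever = trial.meta["lever_arm_m"]
        est = estimate_ankle_moment(trial.forefoot_force["left"], lever)
        truth = trial.ankle_moment["left"]
        assert abs(int(np.argmax(est)) - int(np.argmax(truth))) <= 2


class TestCalibration:
    def _constant_peak_trial(self, profile, peak_cv=0.0):
        return generate_gait_trial(profile, duration=30, seed=4, peak_cv=peak_cv)

    def test_constant_peaks_give_that_peak(self, profile):
        trial = self._constant_peak_trial(profile)
        cal = calibrate_peak_moment(trial, 20.0, lever_arm=trial.meta["lever_arm_m"])
        expected = trial.meta["configured_peaks_nm"]["left"]
        assert cal.mean_peak_moment["left"] == pytest.approx(expected, rel=1e-3)

    def test_mean_of_three_stride_peaks(self):
        # three strides with estimated-moment peaks 1.0, 1.2, 1.4 Nm
        lever = 0.1
        force = np.zeros(300)
        for k, peak_nm in enumerate([1.0, 1.2, 1.4]):
            # 61-point half-sine hits its maximum exactly at the midpoint
            force[100 * k + 20 : 100 * k + 81] = peak_nm / lever * np.sin(
                np.linspace(0, np.pi, 61)
            )
        from exoresist.datatypes import GaitTrial

        trial = GaitTrial(
            sample_rate=100,
            forefoot_force={"left": force, "right": force.copy()},
            ankle_moment={"left": force * lever, "right": force * lever},
        )
        cal = calibrate_peak_moment(trial, 0.5, lever_arm=lever)
        assert cal.mean_peak_moment["left"] == pytest.approx(1.2, rel=1e-9)
        assert cal.strides_used["left"] == 3

    def test_noisy_trial_recovers_configured_mean_within_3pct(self, profile):
        trial = generate_gait_trial(
            profile, duration=120, seed=13, peak_cv=0.1
        )
        cal = calibrate_peak_moment(trial, 20.0, lever_arm=trial.meta["lever_arm_m"])
        for limb in trial.limbs:
            assert cal.mean_peak_moment[limb] == pytest.approx(
                trial.meta["configured_peaks_nm"][limb], rel=0.03
            )

    def test_no_stance_raises_calibration_error(self):
        from exoresist.datatypes import GaitTrial

        z = np.zeros(100)
        trial = GaitTrial(
            sample_rate=100, forefoot_force={"left": z}, ankle_moment={"left": z}
        )
        with pytest.raises(CalibrationError):
            calibrate_peak_moment(trial, 10.0)


class TestTorqueLaw:
    @pytest.mark.parametrize(
        "fraction,expected", [(1.0, 0.1), (0.5, 0.05), (0.0, 0.0)]
    )
    def test_proportional_mapping_at_prescribed_level(self, fraction, expected):
        config = ControllerConfig(resistance_nmkg=0.1, body_mass=50.0)
        assert compute_resistance_torque(fraction, config) == pytest.approx(expected)

    def test_fractions_above_one_are_clipped(self):
        config = ControllerConfig(resistance_nmkg=0.1, body_mass=50.0)
        assert compute_resistance_torque(1.7, config) == pytest.approx(0.1)

    @settings(derandomize=True, max_examples=50)
    @given(
        frac=st.lists(
            st.floats(-0.5, 2.0, allow_subnormal=False), min_size=2, max_size=30
        ),
        r=st.floats(0.01, 0.3, allow_subnormal=False),
    )
    def test_output_bounded_monotone_and_scales_with_r(self, frac, r):
        frac = np.asarray(frac)
        config = ControllerConfig(resistance_nmkg=r, body_mass=40.0)
        tau = compute_resistance_torque(frac, config)
        assert np.all((tau >= 0) & (tau <= r + 1e-12))
        order = np.argsort(frac)
        assert np.all(np.diff(tau[order]) >= -1e-12)  # monotone in fraction
        double = ControllerConfig(resistance_nmkg=2 * r, body_mass=40.0)
        np.testing.assert_allclose(
            compute_resistance_torque(frac, double), 2 * tau, rtol=1e-12
        )


class TestRunSession:
    def _fitted(self, profile, trial, r=0.1):
        ctrl = ProportionalResistanceController(
            resistance_nmkg=r, body_mass=profile.body_mass
        )
        return ctrl.fit(trial)

    def test_zero_resistance_gives_zero_torque(self, profile):
        trial = generate_gait_trial(profile, duration=20, seed=1)
        result = self._fitted(profile, trial, r=0.0).transform(trial)
        for limb in result.limbs:
            assert np.all(result.torque_nm[limb] == 0.0)

    def test_noiseless_calibration_trial_reaches_prescription_every_stride(
        self, profile
    ):
        trial = generate_gait_trial(profile, duration=30, seed=2, peak_cv=0.0)
        ctrl = self._fitted(profile, trial)
        result = ctrl.transform(trial)
        prescribed = 0.1 * profile.body_mass
        for limb in result.limbs:
            np.testing.assert_allclose(
                result.stride_peak_torque_nm[limb], prescribed, rtol=1e-6
            )

    def test_swing_torque_exactly_zero_and_bounds_hold(self, profile):
        trial = generate_gait_trial(profile, duration=30, seed=3, peak_cv=0.2)
        result = self._fitted(profile, trial).transform(trial)
        cap = 0.1 * profile.body_mass
        for limb in result.limbs:
            tau = result.torque_nm[limb]
            assert np.all(tau[~result.stance[limb]] == 0.0)
            assert np.all((tau >= 0) & (tau <= cap * (1 + 1e-12)))

    def test_reaching_fraction_matches_biological_peak_fraction(self, profile):
        # strides reaching 95% of prescribed torque are exactly those whose
        # biological peak reaches 95% of the calibrated peak
        cal_trial = generate_gait_trial(profile, duration=120, seed=5, peak_cv=0.2)
        ctrl = self._fitted(profile, cal_trial)
        trial = generate_gait_trial(profile, duration=120, seed=6, peak_cv=0.2)
        result = ctrl.transform(trial)
        prescribed = 0.1 * profile.body_mass
        for limb in result.limbs:
            reached = np.mean(
                result.stride_peak_torque_nm[limb] >= 0.95 * prescribed
            )
            _, iv = detect_stance(
                trial.forefoot_force[limb], 20.0,
                sample_rate=trial.sample_rate, min_duration_s=0.1,
            )
            bio_peaks = np.array(
                [trial.ankle_moment[limb][a:b].max() for a, b in iv]
            )
            bio_frac = np.mean(
                bio_peaks >= 0.95 * ctrl.calibration_.mean_peak_moment[limb]
            )
            assert reached == pytest.approx(bio_frac, abs=0.02)

    def test_mismatched_limbs_raise_configuration_error(self, profile):
        trial = generate_gait_trial(profile, duration=10, seed=1)
        cal = CalibrationResult(
            mean_peak_moment={"left": 40.0}, strides_used={"left": 5}
        )
        with pytest.raises(ConfigurationError):
            run_session(trial, cal, ControllerConfig(0.1, 50.0))

    def test_transform_before_fit_raises(self, profile):
        trial = generate_gait_trial(profile, duration=10, seed=1)
        with pytest.raises(CalibrationError):
            ProportionalResistanceController().transform(trial)

    def test_sklearn_param_interface(self):
        ctrl = ProportionalResistanceController(resistance_nmkg=0.2)
        assert ctrl.get_params()["resistance_nmkg"] == 0.2
        ctrl.set_params(resistance_nmkg=0.05)
        assert ctrl.resistance_nmkg == 0.05
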