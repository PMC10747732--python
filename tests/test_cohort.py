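import dataclasses

import numpy as np
import pytest
from scipy import stats

from runload.cohort import (FOREFOOT, HEEL, CohortConfig, TrialSpec,
                            ground_truth_forces, sample_cohort, sample_trials,
                            synthesize_kinematics)
from runload.fourier import FourierCode, N_HARMONICS


def _harmonic_amplitude(code, k):
    return float(np.hypot(code.sine[k - 1], code.cosine[k - 1]))


def _trial_at_speed(runner, speed, style, config):
    f_step = config.step_freq_intercept + config.step_freq_slope * speed
    duty = float(np.clip(config.duty_intercept + config.duty_slope * speed,
                         *config.duty_clip))
    return TrialSpec("T_sweep", runner.runner_id, speed, 2.0 / f_step,
                     2.0 * np.pi * f_step, duty, style)


class TestSampleCohort:
    def test_default_study_size_gives_30_female_48_male(self, cohort_config):
        cohort = sample_cohort(78, seed=1, config=cohort_config)
        sexes = [p.sex for p in cohort]
        assert sexes.count("female") == 30
        assert sexes.count("male") == 48

    def test_empty_cohort(self, cohort_config):
        assert sample_cohort(0, seed=1, config=cohort_config) == []

    def test_negative_count_rejected(self, cohort_config):
        with pytest.raises(ValueError):
            sample_cohort(-1, seed=1, config=cohort_config)

    def test_bmi_consistent_and_lengths_positive(self, cohort_config):
        for p in sample_cohort(50, seed=2, config=cohort_config):
            assert p.bmi == pytest.approx(p.mass / p.stature**2, rel=1e-9)
            assert 0 < p.thigh_length < p.stature
            assert 0 < p.shank_length < p.stature
            assert 0 < p.foot_length < p.stature

    def test_monte_carlo_stature_matches_configured_mean(self, cohort_config):
        cohort = sample_cohort(10000, seed=3, config=cohort_config)
        for sex, params in (("female", cohort_config.female),
                            ("male", cohort_config.male)):
            vals = np.array([p.stature for p in cohort if p.sex == sex])
            se = params.stature_sd / np.sqrt(vals.size)
            assert abs(vals.mean() - params.stature_mean) < 3 * se

    def test_determinism(self, cohort_config):
        a = sample_cohort(20, seed=9, config=cohort_config)
        b = sample_cohort(20, seed=9, config=cohort_config)
        assert a == b


class TestSampleTrials:
    def test_default_replication_count(self, cohort_config):
        cohort = sample_cohort(78, seed=1, config=cohort_config)
        trials = sample_trials(cohort, 285, seed=2, config=cohort_config)
        assert len(trials) == 285
        ids = {p.runner_id for p in cohort}
        assert all(t.runner_id in ids for t in trials)

    def test_degenerate_speed_range(self, runner, cohort_config):
        (t,) = sample_trials([runner], 1, (10.0, 10.0), seed=4,
                             config=cohort_config)
        assert t.speed == 10.0

    def test_empty_cohort_rejected(self, cohort_config):
        with pytest.raises(ValueError):
            sample_trials([], 5, (6, 20), seed=1, config=cohort_config)

    def test_speed_distribution_uniform(self, cohort_config):
        cohort = sample_cohort(30, seed=5, config=cohort_config)
        trials = sample_trials(cohort, 10000, (6.0, 20.0), seed=6,
                               config=cohort_config)
        speeds = np.array([t.speed for t in trials])
        stat = stats.kstest(speeds, stats.uniform(6.0, 14.0).cdf)
        assert stat.pvalue > 0.01

    def test_angular_step_frequency_invariant(self, cohort_config):
        cohort = sample_cohort(5, seed=7, config=cohort_config)
        for t in sample_trials(cohort, 40, seed=8, config=cohort_config):
            assert t.angular_step_frequency == pytest.approx(
                2.0 * np.pi / (t.stride_period / 2.0), rel=1e-9)
            assert 0.2 <= t.duty_factor <= 0.45
            assert 6.0 <= t.speed <= 20.0


class TestSynthesizeKinematics:
    def test_band_limited_round_trip(self, kinematics):
        from runload.fourier import fourier_compress
        t = np.arange(200) / 200 * kinematics.stride_period
        for code in kinematics.channels.values():
            rec = fourier_compress(code.evaluate(t),
                                   kinematics.fundamental_frequency)
            assert np.allclose(rec.coefficients, code.coefficients, atol=1e-9)

    def test_coefficient_counts(self, kinematics):
        for code in kinematics.channels.values():
            assert len(code.sine) == N_HARMONICS
            assert len(code.cosine) == N_HARMONICS

    def test_torso_vertical_dominated_by_second_harmonic(self, kinematics):
        code = kinematics.channels["pelvis_vert"]
        assert _harmonic_amplitude(code, 2) > _harmonic_amplitude(code, 1)

    def test_limb_channels_dominated_by_first_harmonic(self, kinematics):
        for name in ("hip_flexion_left", "shoulder_flexion_left"):
            code = kinematics.channels[name]
            assert _harmonic_amplitude(code, 1) > _harmonic_amplitude(code, 2)

    def test_strike_style_touches_only_ankle_channels(self, runner, trial,
                                                      cohort_config):
        heel = dataclasses.replace(trial, strike_style=HEEL)
        fore = dataclasses.replace(trial, strike_style=FOREFOOT)
        kh = synthesize_kinematics(runner, heel, seed=7, config=cohort_config)
        kf = synthesize_kinematics(runner, fore, seed=7, config=cohort_config)
        assert not np.allclose(kh.channels["ankle_angle_left"].coefficients,
                               kf.channels["ankle_angle_left"].coefficients)
        for name in ("shoulder_flexion_left", "knee_flexion_left",
                     "pelvis_vert", "trunk_lean"):
            assert np.array_equal(kh.channels[name].coefficients,
                                  kf.channels[name].coefficients)

    def test_determinism(self, runner, trial, cohort_config):
        a = synthesize_kinematics(runner, trial, seed=7, config=cohort_config)
        b = synthesize_kinematics(runner, trial, seed=7, config=cohort_config)
        for name in a.channels:
            assert np.array_equal(a.channels[name].coefficients,
                                  b.channels[name].coefficients)


class TestGroundTruthForces:
    def test_zero_knee_flexion_gives_zero_patella_force(self, runner, trial,
                                                        kinematics,
                                                        cohort_config):
        zero5 = (0.0,) * 5
        channels = dict(kinematics.channels)
        for side in ("left", "right"):
            channels[f"knee_flexion_{side}"] = FourierCode(
                0.0, zero5, zero5, kinematics.fundamental_frequency)
        kin = dataclasses.replace(kinematics, channels=channels)
        f = ground_truth_forces(runner, trial, kin, cohort_config)
        assert f.patella_force_left == 0.0
        assert f.patella_force_right == 0.0

    def test_impulse_balance_of_vertical_grf(self, trial, cohort_config):
        # integral of the stance half-sine over a step must equal g * step
        # period per unit mass (quadrature oracle)
        from scipy.integrate import quad
        t_c = trial.duty_factor * trial.step_period
        amp = np.pi / (2.0 * trial.duty_factor)
        integral, _ = quad(
            lambda tau: cohort_config.gravity * amp * np.sin(np.pi * tau / t_c),
            0.0, t_c)
        expected = cohort_config.gravity * trial.step_period
        assert abs(integral - expected) / expected < 1e-6

    def test_mass_normalization_invariance(self, runner, trial, kinematics,
                                           cohort_config):
        heavier = dataclasses.replace(runner, mass=2 * runner.mass,
                                      bmi=2 * runner.bmi)
        f1 = ground_truth_forces(runner, trial, kinematics, cohort_config)
        f2 = ground_truth_forces(heavier, trial, kinematics, cohort_config)
        assert f1 == dataclasses.replace(f2, trial_id=f1.trial_id)

    def test_left_right_symmetry_under_default(self, runner, trial,
                                               kinematics, cohort_config):
        f = ground_truth_forces(runner, trial, kinematics, cohort_config)
        assert f.patella_force_left == pytest.approx(f.patella_force_right,
                                                     rel=1e-9)
        assert f.achilles_force_left == pytest.approx(f.achilles_force_right,
                                                      rel=1e-9)

    @pytest.mark.parametrize("style", [HEEL, FOREFOOT])
    def test_forces_increase_with_speed(self, runner, cohort_config, style):
        prev = (0.0, 0.0)
        for speed in np.linspace(6.0, 20.0, 15):
            t = _trial_at_speed(runner, speed, style, cohort_config)
            kin = synthesize_kinematics(runner, t, seed=7,
                                        config=cohort_config)
            f = ground_truth_forces(runner, t, kin, cohort_config)
            assert f.patella_force_left > prev[0]
            assert f.achilles_force_left > prev[1]
            prev = (f.patella_force_left, f.achilles_force_left)

    def test_forefoot_loads_achilles_more_than_heel(self, runner, trial,
                                                    cohort_config):
        heel = dataclasses.replace(trial, strike_style=HEEL)
        fore = dataclasses.replace(trial, strike_style=FOREFOOT)
        kh = synthesize_kinematics(runner, heel, seed=7, config=cohort_config)
        kf = synthesize_kinematics(runner, fore, seed=7, config=cohort_config)
        fh = ground_truth_forces(runner, heel, kh, cohort_config)
        ff = ground_truth_forces(runner, fore, kf, cohort_config)
        assert ff.achilles_force_left > fh.achilles_force_left

    def test_invalid_duty_factor_rejected(self, runner):
        with pytest.raises(ValueError):
            TrialSpec("T_bad", runner.runner_id, 10.0, 0.7,
                      2.0 * np.pi / 0.35, 1.2, HEEL)
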