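"""Synthetic gait generator: schedules, signatures, augmentation, IO."""

import numpy as np
import pytest

from gaitevents import (SubjectSpec, add_sensor_noise, apply_random_rotation,
                        generate_cohort, read_trial, rotate_imu,
                        simulate_trial, write_trial)
from gaitevents.synthetic import DEFAULT_GROUP_SIZES, LOCATIONS


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        a = generate_cohort(3, {g: 1.0 for g in DEFAULT_GROUP_SIZES}, seed=7)
        b = generate_cohort(3, {g: 1.0 for g in DEFAULT_GROUP_SIZES}, seed=7)
        assert a == b
        assert len(a) == 3

    def test_group_counts_near_expectation(self):
        cohort = generate_cohort(157, seed=1)
        n_ya = sum(s.group == "YA" for s in cohort)
        # expectation 157 * 42/157 = 42; allow > 3 binomial SDs
        assert abs(n_ya - 42) <= 18

    def test_pathology_slower_and_more_asymmetric_than_ya(self):
        cohort = generate_cohort(400, seed=2)
        by_group = {}
        for s in cohort:
            by_group.setdefault(s.group, []).append(s)
        cad = {g: np.mean([s.cadence_hz for s in v]) for g, v in by_group.items()}
        asym = {g: np.mean([s.asymmetry for s in v]) for g, v in by_group.items()}
        assert cad["PD"] < cad["YA"] and cad["stroke"] < cad["YA"]
        assert asym["stroke"] > asym["YA"]

    @pytest.mark.parametrize("bad", [0, -1])
    def test_invalid_subject_count(self, bad):
        with pytest.raises(ValueError):
            generate_cohort(bad)

    def test_invalid_weights(self):
        with pytest.raises(ValueError):
            generate_cohort(3, {"YA": -1.0})
        with pytest.raises(ValueError):
            generate_cohort(3, {"YA": 0.0})


class TestSimulateTrial:
    def test_stride_times_match_cadence(self, clean_trial):
        for foot in ("left", "right"):
            ics = clean_trial.truth[foot].ic_times
            assert np.all(np.abs(np.diff(ics) - 1.0) <= 1.0 / clean_trial.fs)

    def test_deterministic_given_seed(self, noisy_subject):
        a = simulate_trial(noisy_subject, "fast", seed=11)
        b = simulate_trial(noisy_subject, "fast", seed=11)
        for loc in LOCATIONS:
            assert np.array_equal(a.imu[loc].X, b.imu[loc].X)
        assert np.array_equal(a.markers["left"].heel, b.markers["left"].heel)

    def test_events_alternate_and_counts_differ_by_one(self, clean_trial):
        for foot in ("left", "right"):
            fe = clean_trial.truth[foot]
            fe.check_alternation()
            assert abs(len(fe.ic_times) - len(fe.fc_times)) == 1

    def test_symmetric_subject_has_equal_feet(self, clean_trial):
        left = np.diff(clean_trial.truth["left"].ic_times)
        right = np.diff(clean_trial.truth["right"].ic_times)
        assert np.all(np.abs(left - right) <= 1.0 / clean_trial.fs)

    def test_speed_conditions_scale_cadence(self, clean_subject):
        strides = {}
        for speed, factor in (("slow", 0.7), ("preferred", 1.0), ("fast", 1.3)):
            trial = simulate_trial(clean_subject, speed, seed=0)
            strides[speed] = np.mean(np.diff(trial.truth["left"].ic_times))
            assert strides[speed] == pytest.approx(1.0 / factor, abs=0.01)

    def test_rotation_does_not_change_truth(self, clean_subject):
        a = simulate_trial(clean_subject, "preferred", seed=5, rotate=True)
        b = simulate_trial(clean_subject, "preferred", seed=5, rotate=False)
        for foot in ("left", "right"):
            assert np.array_equal(a.truth[foot].ic_times, b.truth[foot].ic_times)
            assert np.array_equal(a.truth[foot].fc_times, b.truth[foot].fc_times)

    def test_marker_vertical_nonnegative(self, clean_trial):
        for foot in ("left", "right"):
            assert clean_trial.markers[foot].heel[:, 2].min() >= 0
            assert clean_trial.markers[foot].toe[:, 2].min() >= 0

    def test_invalid_arguments(self, clean_subject):
        with pytest.raises(ValueError):
            simulate_trial(clean_subject, "sprint")
        with pytest.raises(ValueError):
            simulate_trial(clean_subject, "slow", fs=50)
        with pytest.raises(ValueError):
            SubjectSpec("X", "YA", "F", cadence_hz=-1.0, stance_fraction=0.6,
                        asymmetry=0.0, noise_sd=0.0)


class TestRotation:
    def test_identity(self, clean_trial):
        imu = clean_trial.imu["left_shank"]
        out = rotate_imu(imu, np.eye(3))
        assert np.allclose(out.X, imu.X)

    def test_isometry(self, clean_trial):
        imu = clean_trial.imu["left_shank"]
        out = apply_random_rotation(imu, seed=9)
        for sl in (slice(0, 3), slice(3, 6)):
            n0 = np.linalg.norm(imu.X[:, sl], axis=1)
            n1 = np.linalg.norm(out.X[:, sl], axis=1)
            assert np.max(np.abs(n1 - n0) / np.maximum(n0, 1e-12)) < 1e-9

    def test_composition(self, clean_trial, rng):
        from scipy.spatial.transform import Rotation
        imu = clean_trial.imu["right_ankle"]
        r1 = Rotation.random(rng=rng).as_matrix()
        r2 = Rotation.random(rng=rng).as_matrix()
        seq = rotate_imu(rotate_imu(imu, r1), r2)
        once = rotate_imu(imu, r2 @ r1)
        assert np.allclose(seq.X, once.X, atol=1e-10)


class TestSensorNoise:
    def test_zero_noise_is_identity(self, clean_trial):
        imu = clean_trial.imu["left_ankle"]
        assert np.array_equal(add_sensor_noise(imu, 0.0, seed=1).X, imu.X)

    def test_noise_sd_matches_request(self):
        from gaitevents import ImuTrial
        imu = ImuTrial(np.zeros((10000, 6)) + 1.0)
        out = add_sensor_noise(imu, 0.1, seed=4)
        sd = (out.X - imu.X).std(axis=0)
        assert np.all(np.abs(sd - 0.1) / 0.1 < 0.05)

    def test_different_seeds_differ(self, clean_trial):
        imu = clean_trial.imu["left_ankle"]
        a = add_sensor_noise(imu, 0.1, seed=1)
        b = add_sensor_noise(imu, 0.1, seed=2)
        assert not np.array_equal(a.X, b.X)

    def test_negative_noise_rejected(self, clean_trial):
        with pytest.raises(ValueError):
            add_sensor_noise(clean_trial.imu["left_ankle"], -0.1)


def test_trial_round_trip(tmp_path, noisy_subject):
    trial = simulate_trial(noisy_subject, "slow", seed=21)
    d = write_trial(trial, tmp_path / "t0")
    back = read_trial(d)
    assert back.speed_condition == "slow"
    assert back.subject == noisy_subject
    for loc in LOCATIONS:
        assert np.allclose(back.imu[loc].X, trial.imu[loc].X, rtol=1e-6)
    for foot in ("left", "right"):
        assert np.allclose(back.markers[foot].toe, trial.markers[foot].toe,
                           rtol=1e-6, atol=1e-8)
        assert np.allclose(back.truth[foot].ic_times,
                           trial.truth[foot].ic_times)
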