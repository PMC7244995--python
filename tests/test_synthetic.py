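"""Synthetic finger-to-nose generator: determinism, severity ordering, bounds."""

import numpy as np
import pytest

from privvae.agreement import NOT_RATABLE, weighted_kappa
from privvae.synthetic import (
    RaterModel,
    SubjectIdentity,
    SyntheticVideoSpec,
    TrajectorySpec,
    grade_trajectory_spec,
    path_deviation,
    random_subject,
    render_frame,
    simulate_dataset,
    simulate_ratings,
    simulate_trajectory,
    simulate_video,
)


class TestTrajectory:
    def test_grade_zero_is_exact_straight_line(self):
        spec = grade_trajectory_spec(0, n_frames=10)
        for seed in (0, 1, 99):
            pts = simulate_trajectory(spec, seed=seed)
            expected = np.linspace(spec.start_point, spec.end_point, 10)
            np.testing.assert_allclose(pts, expected, atol=1e-12)
            np.testing.assert_allclose(pts[-1], spec.end_point, atol=1e-12)

    def test_deterministic_given_spec_and_seed(self):
        spec = grade_trajectory_spec(3, n_frames=25)
        a = simulate_trajectory(spec, seed=11)
        b = simulate_trajectory(spec, seed=11)
        np.testing.assert_array_equal(a, b)
        c = simulate_trajectory(spec, seed=12)
        assert not np.array_equal(a, c)

    def test_starts_exactly_at_start_and_ends_near_nose(self):
        spec = grade_trajectory_spec(4, n_frames=30)
        for seed in range(20):
            pts = simulate_trajectory(spec, seed=seed)
            np.testing.assert_allclose(pts[0], spec.start_point, atol=1e-12)
            end_err = np.linalg.norm(pts[-1] - np.asarray(spec.end_point))
            assert end_err <= spec.jitter_sd + spec.tremor_amplitude + 1e-9

    def test_severe_grade_deviates_more_than_mild(self):
        """Monte-Carlo over 200 seeds: grade 4 >> grade 1 path deviation."""
        dev = {}
        for grade in (1, 4):
            spec = grade_trajectory_spec(grade, n_frames=30)
            dev[grade] = np.mean([
                path_deviation(simulate_trajectory(spec, seed=s),
                               spec.start_point, spec.end_point)
                for s in range(200)
            ])
        assert dev[4] > dev[1]

    def test_mean_deviation_monotone_in_grade(self):
        means = []
        for grade in range(5):
            spec = grade_trajectory_spec(grade, n_frames=30)
            means.append(np.mean([
                path_deviation(simulate_trajectory(spec, seed=s),
                               spec.start_point, spec.end_point)
                for s in range(100)
            ]))
        # grade 0 is on the line exactly; only projection round-off remains
        assert means[0] < 1e-12
        assert all(means[g] < means[g + 1] for g in range(4))

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="n_frames"):
            TrajectorySpec(n_frames=1, start_point=(0, 0), end_point=(1, 1))


class TestRenderFrame:
    @pytest.mark.parametrize("channels", [3, 4])
    def test_shape_and_value_bounds(self, channels):
        subj = SubjectIdentity("s0")
        frame = render_frame(subj, (30.0, 30.0), 64, channels)
        assert frame.shape == (64, 64, channels)
        assert frame.min() >= 0.0 and frame.max() <= 1.0

    def test_bounds_hold_for_random_specs(self, rng):
        for _ in range(100):
            subj = random_subject(rng, "s")
            tip = rng.uniform(0, 63, size=2)
            frame = render_frame(subj, tip, 64, int(rng.choice([3, 4])))
            assert frame.min() >= 0.0 and frame.max() <= 1.0

    def test_background_seed_changes_only_background(self):
        a = SubjectIdentity("a", background_pattern_seed=1)
        b = SubjectIdentity("a", background_pattern_seed=2)
        tip = (40.0, 20.0)
        fa = render_frame(a, tip, 64, 3)
        fb = render_frame(b, tip, 64, 3)
        diff = np.any(fa != fb, axis=-1)
        assert diff.any()  # backgrounds differ
        # pixels covered by the arm (known skin tone) are identical
        tone = np.asarray(a.skin_tone, dtype=np.float32)
        arm = np.all(np.abs(fa - np.round(tone * 255) / 255) < 1e-6, axis=-1)
        assert arm.any()
        assert not diff[arm].any()

    def test_depth_channel_marks_arm_and_fingertip(self):
        subj = SubjectIdentity("s0", body_depth_offset=0.6)
        frame = render_frame(subj, (40.0, 20.0), 64, 4)
        depth = frame[..., 3]
        assert depth.max() == pytest.approx(0.9, abs=1 / 255)
        assert (depth == 0).mean() > 0.5  # background dominates

    def test_out_of_bounds_fingertip_warns_and_clips(self):
        subj = SubjectIdentity("s0")
        with pytest.warns(UserWarning, match="clipping"):
            frame = render_frame(subj, (200.0, -5.0), 64, 3)
        assert frame.shape == (64, 64, 3)


class TestSimulateVideo:
    def _spec(self, grade=2, seed=5, n_frames=8):
        subj = SubjectIdentity("s0", nose_target=(16.0, 48.0))
        traj = grade_trajectory_spec(grade, n_frames=n_frames,
                                     end_point=subj.nose_target)
        return SyntheticVideoSpec(subject=subj, grade=grade, trajectory=traj,
                                  resolution=64, channels=4, seed=seed)

    def test_declared_shape(self):
        frames, spec = simulate_video(self._spec(n_frames=30))
        assert frames.shape == (30, 64, 64, 4)

    def test_bitwise_reproducible(self):
        f1, _ = simulate_video(self._spec())
        f2, _ = simulate_video(self._spec())
        assert f1.tobytes() == f2.tobytes()

    def test_identity_change_leaves_fingertip_path_unchanged(self):
        spec = self._spec()
        other_subject = SubjectIdentity(
            "s1", limb_thickness=7.0, skin_tone=(0.3, 0.25, 0.2),
            background_pattern_seed=77, nose_target=spec.subject.nose_target,
        )
        spec2 = SyntheticVideoSpec(
            subject=other_subject, grade=spec.grade, trajectory=spec.trajectory,
            resolution=spec.resolution, channels=spec.channels, seed=spec.seed,
        )
        p1 = simulate_trajectory(spec.trajectory, spec.seed)
        p2 = simulate_trajectory(spec2.trajectory, spec2.seed)
        np.testing.assert_array_equal(p1, p2)

    def test_dataset_grade_deviation_monotone(self):
        """Recompute per-grade path deviation from the stored specs."""
        videos = simulate_dataset(20, seed=3, n_frames=20)
        by_grade = {}
        for _, spec in videos:
            pts = simulate_trajectory(spec.trajectory, spec.seed)
            d = path_deviation(pts, spec.trajectory.start_point,
                               spec.trajectory.end_point)
            by_grade.setdefault(spec.grade, []).append(d)
        means = [np.mean(by_grade[g]) for g in range(5)]
        assert all(means[g] <= means[g + 1] for g in range(4))
        assert means[0] < 1e-12  # exact line up to projection round-off

    def test_invalid_specs_rejected(self):
        subj = SubjectIdentity("s0", nose_target=(100.0, 10.0))
        traj = grade_trajectory_spec(0)
        with pytest.raises(ValueError, match="nose_target"):
            SyntheticVideoSpec(subject=subj, grade=0, trajectory=traj,
                               resolution=64, channels=4, seed=0)
        with pytest.raises(ValueError, match="power of two"):
            SyntheticVideoSpec(subject=SubjectIdentity("s"), grade=0,
                               trajectory=traj, resolution=48, channels=4, seed=0)


class TestSimulateRatings:
    def test_noiseless_raters_reproduce_true_grades(self):
        grades = [0, 1, 2, 3, 4, 2, 1]
        table = simulate_ratings(grades, [RaterModel(seed=1), RaterModel(seed=2)])
        for rater in table.rater_ids:
            np.testing.assert_array_equal(table.column(rater), grades)

    def test_all_not_ratable_at_probability_one(self):
        table = simulate_ratings([1, 2, 3], [RaterModel(not_ratable_prob=1.0)])
        assert np.isnan(table.data.to_numpy()).all()

    def test_two_noiseless_raters_have_perfect_kappa(self):
        grades = [0, 1, 2, 3, 4, 0, 2]
        table = simulate_ratings(grades, [RaterModel(seed=1), RaterModel(seed=2)])
        res = weighted_kappa(table.column("rater00"), table.column("rater01"))
        assert res.kappa == pytest.approx(1.0)

    def test_deterministic_given_rater_seeds(self):
        raters = [RaterModel(miscode_sd=0.8, not_ratable_prob=0.2, seed=9)]
        t1 = simulate_ratings([0, 2, 4] * 10, raters)
        t2 = simulate_ratings([0, 2, 4] * 10, raters)
        assert t1.data.equals(t2.data)

    def test_bias_shifts_ratings(self):
        table = simulate_ratings([2] * 10, [RaterModel(bias=1.0)])
        np.testing.assert_array_equal(table.column("rater00"), [3] * 10)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            simulate_ratings([], [RaterModel()])
        with pytest.raises(ValueError, match="at least one"):
            simulate_ratings([1], [])
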