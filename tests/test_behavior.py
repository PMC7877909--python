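"""Kinematic closed forms, rigid-motion invariance, group-activity counting
on a planted design, and the ANOVA fixtures."""

import math

import numpy as np
import pytest
from scipy import stats

from mbonmap import synthetic as syn
from mbonmap.behavior import (Trajectory, group_activity, kinematic_features,
                              one_way_anova)


def straight_traj(v=5.0, duration=10.0, fps=33.0, heading=0.3):
    n = int(round(fps * duration)) + 1
    t = np.arange(n) / fps
    pos = np.column_stack([v * t * np.cos(heading), v * t * np.sin(heading)])
    return Trajectory("f", pos, fps=fps)


class TestKinematics:
    def test_stationary_fly_is_all_zero(self):
        pos = np.tile([3.0, -2.0], (100, 1))
        f = kinematic_features(Trajectory("f", pos, fps=33), 1)
        assert (f.pathlength, f.mean_velocity, f.mean_angular_velocity) == (0, 0, 0)

    def test_straight_line_closed_form(self):
        f = kinematic_features(straight_traj(), smoothing_window=1)
        assert f.pathlength == pytest.approx(50.0)
        assert f.mean_velocity == pytest.approx(5.0)
        assert f.mean_angular_velocity == pytest.approx(0.0, abs=1e-9)

    def test_circle_angular_velocity_closed_form(self):
        trajs, _ = syn.generate_trajectories(
            1, syn.Circle(radius=8.0, period=20.0), fps=33, duration=20, seed=0)
        f = kinematic_features(trajs[0], smoothing_window=1)
        assert f.mean_angular_velocity == pytest.approx(18.0, rel=0.02)

    def test_rigid_motion_invariance(self, rng):
        trajs, _ = syn.generate_trajectories(
            1, syn.CorrelatedWalk(), fps=33, duration=10, seed=5)
        base = kinematic_features(trajs[0], 5)
        theta = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        moved = trajs[0].positions @ R.T + np.array([13.0, -4.0])
        f2 = kinematic_features(Trajectory("f", moved, fps=33), 5)
        assert f2.pathlength == pytest.approx(base.pathlength, rel=1e-9)
        assert f2.mean_velocity == pytest.approx(base.mean_velocity, rel=1e-9)
        assert f2.mean_angular_velocity == pytest.approx(
            base.mean_angular_velocity, rel=1e-6)

    def test_velocity_bounded_by_max_step(self):
        traj = straight_traj(v=7.0)
        f = kinematic_features(traj, 1)
        max_step = np.linalg.norm(np.diff(traj.positions, axis=0),
                                  axis=1).max()
        assert f.mean_velocity <= traj.fps * max_step + 1e-12

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            kinematic_features(straight_traj(), smoothing_window=4)

    def test_too_short_trajectory_rejected(self):
        with pytest.raises(ValueError, match="2 frames"):
            kinematic_features(Trajectory("f", np.zeros((1, 2)), fps=33), 1)


class TestGroupActivity:
    def make_replicate(self, moving_mask, n_frames=331, fps=33.0):
        """10 flies; moving_mask[fly] gives per-frame movement booleans."""
        flies = []
        for i, move in enumerate(moving_mask):
            steps = np.where(move, 0.2, 0.0)
            x = np.concatenate([[0.0], np.cumsum(steps)])[: n_frames]
            pos = np.column_stack([x, np.zeros_like(x)])
            flies.append(Trajectory(f"f{i}", pos, fps=fps))
        return flies

    def test_all_stationary_gives_zero(self):
        rep = self.make_replicate([np.zeros(330, bool)] * 10)
        s = group_activity([rep], bin_width=1.0)
        assert (s.activity == 0).all()

    def test_all_moving_saturates_at_group_size(self):
        rep = self.make_replicate([np.ones(330, bool)] * 10)
        s = group_activity([rep], bin_width=1.0)
        assert (s.activity == 10).all()

    def test_planted_bin_design_matches_frame_oracle(self):
        # exactly 4 of 10 flies move during bin 3 (frames 99..131), only
        n_frames, fps = 331, 33.0
        masks = []
        for i in range(10):
            m = np.zeros(n_frames - 1, bool)
            if i < 4:
                m[99:132] = True
            masks.append(m)
        rep = self.make_replicate(masks, n_frames=n_frames, fps=fps)
        s = group_activity([rep], bin_width=1.0)
        expected = np.zeros(10)
        expected[3] = 4.0
        np.testing.assert_allclose(s.activity, expected)

    def test_replicate_averaging(self):
        rep_a = self.make_replicate([np.ones(330, bool)] * 10)
        rep_b = self.make_replicate([np.zeros(330, bool)] * 10)
        s = group_activity([rep_a, rep_b], bin_width=1.0)
        assert (s.activity == 5.0).all()
        assert s.n_replicates == 2

    def test_mixed_frame_rates_rejected(self):
        rep = self.make_replicate([np.zeros(330, bool)] * 2)
        odd = Trajectory("x", rep[0].positions, fps=30.0)
        with pytest.raises(ValueError, match="share fps"):
            group_activity([[rep[0], odd]])


class TestAnova:
    def test_hand_computed_fixture(self):
        res = one_way_anova([np.array([1.0, 2, 3]), np.array([2.0, 3, 4]),
                             np.array([3.0, 4, 5])])
        assert res.F == pytest.approx(3.0)
        assert (res.df_between, res.df_within) == (2, 6)
        assert res.p == pytest.approx(stats.f.sf(3.0, 2, 6))
        assert len(res.tukey) == 3

    def test_identical_groups_give_zero_f(self):
        res = one_way_anova([np.array([1.0, 2, 3])] * 3)
        assert res.F == 0.0

    def test_two_groups_f_equals_t_squared(self, rng):
        for _ in range(10):
            a = rng.normal(size=12)
            b = rng.normal(loc=0.5, size=9)
            res = one_way_anova([a, b])
            t, _ = stats.ttest_ind(a, b)
            assert res.F == pytest.approx(t ** 2, rel=1e-9)

    def test_agrees_with_reference_implementation(self, rng):
        groups = [rng.normal(size=8), rng.normal(1.0, size=10),
                  rng.normal(-0.5, size=9)]
        res = one_way_anova(groups)
        F_ref, p_ref = stats.f_oneway(*groups)
        assert res.F == pytest.approx(F_ref, rel=1e-10)
        assert res.p == pytest.approx(p_ref, rel=1e-10)

    def test_zero_within_variance_reports_infinite_f(self):
        res = one_way_anova([np.array([1.0, 1.0]), np.array([2.0, 2.0])])
        assert math.isinf(res.F) and res.p == 0.0

    def test_all_identical_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            one_way_anova([np.array([2.0, 2.0]), np.array([2.0, 2.0])])

    def test_speed_difference_recovered_from_trajectories(self):
        # planted genotype effect on walking speed must reach significance
        rejections = 0
        for seed in range(20):
            groups = []
            for g, mu in enumerate((4.0, 4.0, 6.0)):
                vels = []
                for i in range(8):
                    trajs, _ = syn.generate_trajectories(
                        1, syn.CorrelatedWalk(mu_speed=mu), fps=33,
                        duration=5, seed=seed * 100 + g * 10 + i)
                    vels.append(kinematic_features(trajs[0], 1).mean_velocity)
                groups.append(np.array(vels))
            if one_way_anova(groups).p < 0.05:
                rejections += 1
        assert rejections >= 19
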