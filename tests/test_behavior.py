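"""Trajectory quantification: heading, displacements, turns, statistics."""

import numpy as np
import pytest

from flexb2b.behavior import (
    angular_displacement,
    behavior_confusion,
    classify_turn,
    compare_phases,
    heading_series,
    linear_displacement,
    max_angular_change,
)
from flexb2b.synth import Trajectory, TrajectorySpec, synth_trajectory


def circle(radius=50.0, n_steps=90, extra_steps=1, jitter=0.0, seed=0):
    """Counterclockwise circle; `extra_steps` past closure so the first and
    last step headings differ by a full 360 degrees."""
    ang = 2 * np.pi * np.arange(n_steps + 1 + extra_steps) / n_steps
    rng = np.random.default_rng(seed)
    r = radius * (1 + jitter * rng.standard_normal(len(ang)))
    t = np.arange(len(ang), dtype=float)
    return Trajectory(t, r * np.cos(ang), r * np.sin(ang))


class TestHeading:
    def test_straight_line_constant_zero(self):
        t = np.arange(10, dtype=float)
        traj = Trajectory(t, 10.0 * t, np.zeros(10))
        h = heading_series(traj)
        np.testing.assert_allclose(h, 0.0, atol=1e-12)

    def test_full_circle_is_360(self):
        traj = circle()
        h = heading_series(traj)
        assert h[-1] - h[0] == pytest.approx(360.0)

    def test_noisy_circle_within_5_degrees(self):
        # coarse sampling keeps step lengths large relative to the jitter
        traj = circle(n_steps=24, jitter=0.01, seed=1)
        h = heading_series(traj)
        assert h[-1] - h[0] == pytest.approx(360.0, abs=5.0)

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            heading_series(Trajectory([0.0], [0.0], [0.0]))


class TestAngularDisplacement:
    def test_synthetic_left_turn_rate_times_time(self):
        spec = TrajectorySpec(command_letter="L", turn_rate=25.0,
                              phase_durations=(10, 10, 10), jitter=0.0,
                              seed=0)
        traj = synth_trajectory(spec)
        ang = angular_displacement(traj, traj.phases["during"])
        assert ang == pytest.approx(250.0, abs=1.0)

    def test_mirror_flips_sign_exactly(self):
        spec = TrajectorySpec(command_letter="L", seed=2)
        traj = synth_trajectory(spec)
        mirrored = Trajectory(traj.t, traj.x, -traj.y)
        a = angular_displacement(traj, traj.phases["during"])
        b = angular_displacement(mirrored, traj.phases["during"])
        assert b == -a

    def test_rotation_invariance(self):
        spec = TrajectorySpec(command_letter="R", seed=4)
        traj = synth_trajectory(spec)
        th = np.radians(73.0)
        rot = Trajectory(
            traj.t,
            np.cos(th) * traj.x - np.sin(th) * traj.y,
            np.sin(th) * traj.x + np.cos(th) * traj.y,
        )
        a = angular_displacement(traj, traj.phases["during"])
        b = angular_displacement(rot, traj.phases["during"])
        assert b == pytest.approx(a, abs=1e-6)
        la = linear_displacement(traj, traj.phases["during"])
        lb = linear_displacement(rot, traj.phases["during"])
        assert lb == pytest.approx(la, rel=1e-12)

    def test_stationary_is_zero(self):
        t = np.arange(20, dtype=float)
        traj = Trajectory(t, np.zeros(20), np.zeros(20))
        assert angular_displacement(traj, (0.0, 19.0)) == 0.0

    def test_empty_window_rejected(self):
        traj = synth_trajectory(TrajectorySpec(seed=0))
        with pytest.raises(ValueError):
            angular_displacement(traj, (5.0, 5.0))


class TestLinearDisplacement:
    def test_straight_segment(self):
        t = np.arange(11, dtype=float)
        traj = Trajectory(t, 10.0 * t, np.zeros(11))
        assert linear_displacement(traj, (0.0, 10.0)) \
            == pytest.approx(100.0)

    def test_out_and_back_counts_path(self):
        t = np.arange(11, dtype=float)
        x = np.concatenate([np.linspace(0, 50, 6),
                            np.linspace(40, 0, 5)])
        traj = Trajectory(t, x, np.zeros(11))
        assert linear_displacement(traj, (0.0, 10.0)) \
            == pytest.approx(100.0)

    def test_circle_circumference(self):
        r = 30.0
        traj = circle(radius=r, n_steps=720, extra_steps=0)
        length = linear_displacement(traj, (traj.t[0], traj.t[-1]))
        assert length == pytest.approx(2 * np.pi * r, rel=1e-3)

    def test_path_at_least_net(self):
        spec = TrajectorySpec(command_letter="L", seed=8)
        traj = synth_trajectory(spec)
        w = traj.phases["during"]
        ii = (traj.t >= w[0]) & (traj.t <= w[1])
        net = np.hypot(traj.x[ii][-1] - traj.x[ii][0],
                       traj.y[ii][-1] - traj.y[ii][0])
        assert linear_displacement(traj, w) >= net - 1e-12


class TestMaxAngularChange:
    def test_monotone_turn_peaks_at_endpoint(self):
        spec = TrajectorySpec(command_letter="L", turn_rate=25.0,
                              phase_durations=(10, 10, 10), jitter=0.0,
                              seed=0)
        traj = synth_trajectory(spec)
        out = max_angular_change(traj, traj.phases)
        assert out["during"] == pytest.approx(250.0, abs=1.0)
        assert out["before"] == 0.0

    def test_transient_peak_not_endpoint(self):
        # +30 deg excursion that returns to +5: the peak counts
        t = np.arange(13, dtype=float)
        headings = np.radians(np.concatenate([
            np.linspace(0, 30, 7), np.linspace(25, 5, 5)]))
        steps = np.stack([2.0 * np.cos(headings), 2.0 * np.sin(headings)])
        x = np.concatenate([[0.0], np.cumsum(steps[0])])
        y = np.concatenate([[0.0], np.cumsum(steps[1])])
        traj = Trajectory(t, x, y)
        out = max_angular_change(traj, {"all": (0.0, 12.0)})
        assert out["all"] == pytest.approx(30.0, abs=1e-9)
        end = max_angular_change(traj, {"all": (0.0, 12.0)},
                                 endpoint=True)
        assert end["all"] == pytest.approx(5.0, abs=1e-9)

    def test_stationary_phases_all_zero(self):
        t = np.arange(30, dtype=float)
        traj = Trajectory(t, np.zeros(30), np.zeros(30))
        out = max_angular_change(traj, {"before": (0, 9), "during": (10, 19),
                                        "after": (20, 29)})
        assert out == {"before": 0.0, "during": 0.0, "after": 0.0}


class TestClassifyTurn:
    @pytest.mark.parametrize("angle,label", [
        (25.0, "L"), (-19.0, "X"), (20.0, "X"), (-20.0, "X"),
        (-20.5, "R"), (0.0, "X"),
    ])
    def test_threshold_rule(self, angle, label):
        assert classify_turn(angle) == label

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_turn(float("nan"))


class TestBehaviorConfusion:
    def test_perfect(self):
        cmds = ["LL", "RR", "LR", "RL"] * 4
        cm = behavior_confusion(cmds, cmds)
        assert cm.accuracy == 1.0

    def test_76_of_80_gives_95(self):
        cmds = [c for c in
                ("LL", "RR", "LR", "RL", "LX", "RX", "XL", "XR")] * 10
        obs = list(cmds)
        for i in range(4):
            obs[i] = "XX"
        cm = behavior_confusion(cmds, obs)
        assert cm.accuracy == pytest.approx(0.95)

    def test_all_xx_is_zero(self):
        cmds = ["LL"] * 10
        cm = behavior_confusion(cmds, ["XX"] * 10)
        assert cm.accuracy == 0.0
        assert cm.counts.shape == (8, 9)

    def test_malformed_labels_rejected(self):
        with pytest.raises(ValueError):
            behavior_confusion(["LL"], ["ZZ"])
        with pytest.raises(ValueError):
            behavior_confusion(["XX"], ["LL"])  # XX cannot be commanded


class TestComparePhases:
    def test_identical_groups_ns(self):
        t, p, stars = compare_phases([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0 and stars == "ns"

    def test_five_sigma_separation_four_stars(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 20)
        b = rng.normal(5, 1, 20)
        _, p, stars = compare_phases(a, b)
        assert p <= 1e-4 and stars == "****"

    def test_star_thresholds(self):
        from flexb2b.behavior import significance_stars
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == "ns"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"

    def test_matches_scipy_student_t(self):
        from scipy import stats
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 2, 12)
        t, p, _ = compare_phases(a, b)
        t2, p2 = stats.ttest_ind(a, b)
        assert (t, p) == (pytest.approx(t2), pytest.approx(p2))
        tw, pw, _ = compare_phases(a, b, welch=True)
        t3, p3 = stats.ttest_ind(a, b, equal_var=False)
        assert (tw, pw) == (pytest.approx(t3), pytest.approx(p3))
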