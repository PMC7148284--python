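import numpy as np
import pytest

from joyddm.behavior import joystick_rt
from joyddm.kinematics import (
    acceleration_time,
    path_length,
    peak_velocity,
    trajectory_metrics,
    velocity_profile,
)
from joyddm.trajectories import Trajectory, synth_trajectory


def make_traj(xy, rate=85.0):
    xy = np.asarray(xy, dtype=float)
    return Trajectory(0, 0, np.arange(len(xy)) / rate, xy[:, 0], xy[:, 1], rate=rate)


class TestVelocityProfile:
    def test_constant_rate_straight_move(self):
        xy = [[0.1 * i, 0.0] for i in range(8)]
        speed = velocity_profile(make_traj(xy))
        assert np.allclose(speed, 0.1 * 85.0)
        assert speed.size == 7

    def test_stationary_is_zero(self):
        assert np.allclose(velocity_profile(make_traj([[0.3, 0.3]] * 10)), 0.0)

    def test_bell_profile_has_single_interior_maximum(self):
        tr = synth_trajectory("left", rt=0.4, stop_time=1.0, peak_speed=6.0)
        speed = velocity_profile(tr)
        moving = speed > 1e-6
        seg = speed[moving]
        i = int(np.argmax(seg))
        assert np.all(np.diff(seg[: i + 1]) >= -1e-9)  # rises to the peak
        assert np.all(np.diff(seg[i:]) <= 1e-9)  # then falls

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            velocity_profile(make_traj([[0, 0]] * 1))


class TestPeakVelocity:
    def test_known_maximum_recovered(self):
        tr = synth_trajectory("up", rt=0.5, stop_time=1.2, peak_speed=12.0)
        pv, pt = peak_velocity(tr)
        assert pv == pytest.approx(12.0, rel=0.02)

    def test_tie_reports_earliest_interval(self):
        xy = [[0, 0], [0.3, 0], [0.3, 0], [0.6, 0], [0.6, 0], [0.6, 0], [0.6, 0]]
        pv, pt = peak_velocity(make_traj(xy), up_to_stop=False)
        assert pt == pytest.approx(0.5 / 85.0)

    def test_monotone_speed_peaks_at_last_interval(self):
        xy = [[0.0, 0], [0.01, 0], [0.03, 0], [0.07, 0], [0.15, 0]]
        _, pt = peak_velocity(make_traj(xy), up_to_stop=False)
        assert pt == pytest.approx(3.5 / 85.0)

    def test_peak_at_least_mean_speed(self, rng):
        for _ in range(20):
            tr = synth_trajectory(
                "right",
                rt=float(rng.uniform(0.3, 0.8)),
                stop_time=2.0,
                peak_speed=float(rng.uniform(4, 12)),
            )
            speed = velocity_profile(tr)
            assert peak_velocity(tr)[0] >= speed.mean()


class TestAccelerationTime:
    def test_constructed_latency_recovered(self):
        # peak at onset + duration/2; crossing at rt
        peak_speed, amp = 8.0, 1.0
        dur = amp * np.pi / (2 * peak_speed)
        tau_cross = dur / np.pi * np.arccos(1 - 0.4 / amp)
        expected = dur / 2 - tau_cross
        tr = synth_trajectory("down", rt=0.5, stop_time=1.3, peak_speed=peak_speed)
        at = acceleration_time(tr, rt=joystick_rt(tr))
        assert at == pytest.approx(expected, abs=1.5 / 85.0)

    def test_peak_before_crossing_flagged(self):
        xy = [[0, 0], [0.15, 0], [0.19, 0], [0.21, 0], [0.22, 0], [0.23, 0]]
        with pytest.warns(UserWarning, match="peak precedes"):
            at = acceleration_time(make_traj(xy), rt=3.5 / 85.0)
        assert at < 0

    def test_no_response_rejected(self):
        with pytest.raises(ValueError):
            acceleration_time(make_traj([[0.0, 0.0]] * 10), rt=float("nan"))


class TestPathLength:
    def test_straight_collinear_path(self):
        xy = [[i / 6, 0.0] for i in range(7)]
        assert path_length(make_traj(xy), up_to_stop=False) == pytest.approx(1.0)

    def test_l_shaped_path(self):
        xy = [[0, 0], [0.5, 0], [1.0, 0], [1.0, 0.5], [1.0, 1.0]]
        assert path_length(make_traj(xy), up_to_stop=False) == pytest.approx(2.0)

    def test_full_deflection_ballistic_movement_is_near_one(self):
        tr = synth_trajectory("right", rt=0.5, stop_time=1.3, amplitude=1.0)
        assert path_length(tr) == pytest.approx(1.0, abs=0.02)

    def test_rotation_invariance(self, rng):
        xy = rng.uniform(-0.7, 0.7, size=(30, 2))
        th = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        a = path_length(make_traj(xy), up_to_stop=False)
        b = path_length(make_traj(xy @ R.T), up_to_stop=False)
        assert a == pytest.approx(b)

    def test_subsampling_never_lengthens(self, rng):
        xy = np.cumsum(rng.normal(0, 0.01, size=(60, 2)), axis=0)
        full = path_length(make_traj(xy), up_to_stop=False)
        sub = path_length(make_traj(xy[::3]), up_to_stop=False)
        assert sub <= full + 1e-12


def test_direction_dependent_peak_speeds_preserve_order(rng):
    """Recovered per-direction mean peak velocities keep the generating order."""
    gen = {"right": 11.0, "up": 9.0, "left": 7.0, "down": 5.0}
    means = {}
    for d, ps in gen.items():
        vals = []
        for _ in range(25):
            tr = synth_trajectory(
                d, rt=float(rng.uniform(0.4, 0.9)), stop_time=2.0,
                peak_speed=float(ps * rng.uniform(0.95, 1.05)),
            )
            vals.append(trajectory_metrics(tr).peak_velocity)
        means[d] = np.mean(vals)
    assert means["right"] > means["up"] > means["left"] > means["down"]
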