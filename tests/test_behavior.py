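import numpy as np
import pandas as pd
import pytest

from joyddm.behavior import (
    classify_choice,
    detect_stop,
    joystick_rt,
    ks_2samp,
    ks_consistency,
    summarize,
)
from joyddm.trajectories import Trajectory, synth_trajectory


def brute_force_ks(x, y):
    pts = np.concatenate([x, y])
    return max(abs(np.mean(x <= t) - np.mean(y <= t)) for t in pts)


def make_traj(xy, rate=85.0):
    xy = np.asarray(xy, dtype=float)
    t = np.arange(len(xy)) / rate
    return Trajectory(0, 0, t, xy[:, 0], xy[:, 1], rate=rate)


class TestJoystickRt:
    def test_recovers_crossing_sample(self):
        tr = synth_trajectory("right", rt=0.5059, stop_time=1.2)
        assert joystick_rt(tr) == pytest.approx(0.5059, abs=1.0 / 85.0)

    def test_no_response_marker_when_radius_never_left(self):
        tr = make_traj([[0.05, 0.0]] * 20)
        assert np.isnan(joystick_rt(tr))

    def test_zero_radius_triggers_at_first_deflection(self):
        xy = [[0.0, 0.0]] * 5 + [[0.01, 0.0]] * 10
        tr = make_traj(xy)
        assert joystick_rt(tr, radius=0.0) == pytest.approx(5 / 85.0)

    def test_onset_offset_subtracted(self):
        tr = synth_trajectory("up", rt=0.6, stop_time=1.3)
        assert joystick_rt(tr, stimulus_onset=0.1) == pytest.approx(0.5, abs=1.5 / 85.0)


class TestDetectStop:
    def test_plateau_end_detected(self):
        xy = [[0.0, 0.0]] * 10 + [[0.5, 0.0]] * 2 + [[0.9, 0.0]] * 6
        tr = make_traj(xy)
        assert detect_stop(tr) == 15  # fourth identical sample at (0.9, 0)

    def test_jittered_trajectory_never_stops(self, rng):
        xy = np.cumsum(rng.uniform(0.001, 0.002, size=(40, 2)), axis=0) + 0.3
        tr = make_traj(np.clip(xy, -1, 1))
        assert detect_stop(tr) is None

    def test_plateau_inside_radius_is_not_a_stop(self):
        xy = [[0.1, 0.1]] * 30  # still, but inside the 20% radius
        tr = make_traj(xy)
        assert detect_stop(tr) is None

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            detect_stop(make_traj([[0.3, 0.0]] * 5), window=6)


class TestClassifyChoice:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            ((0.9, 0.1), "right"),
            ((-0.7, -0.01), "left"),
            ((0.02, 0.8), "up"),
            ((0.1, -0.6), "down"),
            ((0.5, 0.5), "up"),  # 45 degree tie -> counter-clockwise winner
            ((-0.5, 0.5), "left"),
            ((-0.5, -0.5), "down"),
            ((0.5, -0.5), "right"),
        ],
    )
    def test_nearest_cardinal(self, pos, expected):
        assert classify_choice(pos) == expected

    def test_origin_rejected(self):
        with pytest.raises(ValueError):
            classify_choice((0.0, 0.0))

    def test_rotation_advances_label_one_step(self, rng):
        order = ["right", "up", "left", "down"]
        for _ in range(50):
            ang = rng.uniform(0, 2 * np.pi)
            r = rng.uniform(0.1, 1.0)
            p = (r * np.cos(ang), r * np.sin(ang))
            p90 = (-p[1], p[0])  # rotate +90 degrees
            i = order.index(classify_choice(p))
            assert classify_choice(p90) == order[(i + 1) % 4]


class TestSummarize:
    def test_toy_arithmetic(self):
        df = pd.DataFrame(
            {
                "session": ["joystick"] * 10,
                "difficulty": ["easy"] * 10,
                "direction": ["up"] * 10,
                "correct": [True] * 10,
                "rt_s": np.arange(0.5, 1.5, 0.1),
            }
        )
        out = summarize(df)
        cell = out[(out["difficulty"] == "easy") & (out["direction"] == "up")].iloc[0]
        assert cell["accuracy"] == 1.0
        assert cell["mean_rt_s"] == pytest.approx(0.95)

    def test_single_trial(self):
        df = pd.DataFrame(
            {
                "session": ["keyboard"],
                "difficulty": ["difficult"],
                "direction": ["left"],
                "correct": [False],
                "rt_s": [1.23],
            }
        )
        out = summarize(df)
        assert set(out["accuracy"]) == {0.0}
        assert set(out["mean_rt_s"]) == {1.23}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame(columns=["session", "difficulty", "direction", "correct", "rt_s"]))

    def test_empty_cells_absent_not_zero(self, tiny_cohort):
        _, trials, _ = tiny_cohort
        out = summarize(trials)
        assert (out["n"] > 0).all()


class TestKs2samp:
    def test_identical_samples(self, rng):
        x = rng.normal(size=50)
        assert ks_2samp(x, x) == 0.0

    def test_disjoint_supports(self):
        assert ks_2samp([1.0, 2.0, 3.0], [10.0, 11.0]) == 1.0

    def test_small_example(self):
        assert ks_2samp([1, 2, 3], [2, 3, 4]) == pytest.approx(1 / 3)

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            x = rng.normal(rng.uniform(-1, 1), 1.0, size=rng.integers(5, 60))
            y = rng.normal(0.0, rng.uniform(0.5, 2.0), size=rng.integers(5, 60))
            d = ks_2samp(x, y)
            assert d == pytest.approx(brute_force_ks(x, y), abs=1e-12)
            assert 0.0 <= d <= 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_2samp([], [1.0])


def _consistency_frame(n_participants, lag_fn, rng):
    rows = []
    for pid in range(1, n_participants + 1):
        lag = lag_fn(pid)
        for diff in ("easy", "difficult"):
            base = 0.6 if diff == "easy" else 0.8
            for ses, extra in (("joystick", lag), ("keyboard", 0.0)):
                rts = base + extra + rng.gamma(2.0, 0.15, size=80)
                correct = rng.uniform(size=80) < 0.8
                for r, c in zip(rts, correct):
                    rows.append((pid, ses, diff, "up", c, r))
    return pd.DataFrame(
        rows, columns=["participant", "session", "difficulty", "direction", "correct", "rt_s"]
    )


class TestKsConsistency:
    def test_identical_distributions_give_zero_d(self, rng):
        df = _consistency_frame(4, lambda pid: 0.0, rng)
        # force exactly equal RT samples across modalities
        joy = df[df["session"] == "joystick"].copy()
        joy["session"] = "keyboard"
        both = pd.concat([df[df["session"] == "joystick"], joy], ignore_index=True)
        res = ks_consistency(both)
        assert np.allclose(res["per_participant"]["ks_d"].dropna(), 0.0)

    def test_participant_specific_lag_correlates_across_difficulty(self, rng):
        df = _consistency_frame(12, lambda pid: 0.05 * pid, rng)
        res = ks_consistency(df)
        assert res["correlations"]["correct"]["r"] > 0.5

    def test_single_participant_reports_missing_correlation(self, rng):
        df = _consistency_frame(1, lambda pid: 0.1, rng)
        res = ks_consistency(df)
        assert res["correlations"]["correct"]["r"] is None
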