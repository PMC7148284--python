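"""Continuous joystick measures: velocity profile, peak velocity,
acceleration time and path length.

Velocity is the raw finite difference of position (no smoothing by default;
an optional moving-average window is available).  Metrics are computed up to
the detected stop index — samples after the stopping rule fires are padding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import detect_stop, joystick_rt
from .trajectories import Trajectory


@dataclass(frozen=True)
class TrajectoryMetrics:
    peak_velocity: float  # normalized units / s
    peak_time: float  # seconds (midpoint of the fastest sample pair)
    acceleration_time: float  # peak_time - rt, seconds
    path_length: float  # normalized units


def _active_slice(traj: Trajectory, up_to_stop: bool) -> Trajectory:
    if not up_to_stop:
        return traj
    stop = detect_stop(traj)
    if stop is None or stop < 1:
        return traj
    return Trajectory(
        traj.participant_id,
        traj.trial_id,
        traj.t[: stop + 1],
        traj.x[: stop + 1],
        traj.y[: stop + 1],
        rate=traj.rate,
    )


def velocity_profile(traj: Trajectory, smooth_window: int = 0) -> np.ndarray:
    """Speed series: Euclidean displacement between consecutive samples over
    the sample period; length n-1.  ``smooth_window`` > 1 applies a centered
    moving average to the speed series."""
    if len(traj) < 2:
        raise ValueError("velocity needs at least 2 samples")
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    dt = np.diff(traj.t)
    speed = np.hypot(dx, dy) / dt
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        speed = np.convolve(speed, kernel, mode="same")
    return speed


def peak_velocity(traj: Trajectory, up_to_stop: bool = True) -> tuple[float, float]:
    """Maximum speed and its time (midpoint of the fastest sample pair).

    Ties go to the earliest interval.
    """
    tr = _active_slice(traj, up_to_stop)
    speed = velocity_profile(tr)
    i = int(np.argmax(speed))  # argmax returns the first maximum
    t_mid = float((tr.t[i] + tr.t[i + 1]) / 2.0)
    return float(speed[i]), t_mid


def acceleration_time(traj: Trajectory, rt: float | None = None) -> float:
    """Latency between the RT (20% radius departure) and the velocity peak.

    Negative values (peak before the radius crossing) are allowed but
    flagged with a warning.
    """
    if rt is None:
        rt = joystick_rt(traj)
    if not np.isfinite(rt):
        raise ValueError("acceleration time undefined without a response")
    _, t_peak = peak_velocity(traj)
    at = float(t_peak - rt)
    if at < 0:
        warnings.warn(
            f"velocity peak precedes the radius crossing (acceleration time {at:.4f} s)",
            stacklevel=2,
        )
    return at


def path_length(traj: Trajectory, up_to_stop: bool = True) -> float:
    """Sum of Euclidean distances between adjacent joystick positions."""
    tr = _active_slice(traj, up_to_stop)
    if len(tr) < 2:
        raise ValueError("path length needs at least 2 samples")
    return float(np.sum(np.hypot(np.diff(tr.x), np.diff(tr.y))))


def trajectory_metrics(traj: Trajectory, rt: float | None = None) -> TrajectoryMetrics:
    if rt is None:
        rt = joystick_rt(traj)
    pv, pt = peak_velocity(traj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        at = float(pt - rt)
    return TrajectoryMetrics(
        peak_velocity=pv, peak_time=pt, acceleration_time=at, path_length=path_length(traj)
    )


def metrics_table(trajs: list[Trajectory], trials: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-trial metric table, joined to condition labels when a trial table
    is supplied."""
    rows = []
    for tr in trajs:
        m = trajectory_metrics(tr)
        rows.append(
            (
                tr.participant_id,
                tr.trial_id,
                joystick_rt(tr),
                m.peak_velocity,
                m.peak_time,
                m.acceleration_time,
                m.path_length,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "participant",
            "trial",
            "rt_s",
            "peak_velocity",
            "peak_time",
            "acceleration_time",
            "path_length",
        ],
    )
    if trials is not None:
        lab = trials.loc[
            trials["session"] == "joystick",
            ["participant", "trial", "difficulty", "direction"],
        ]
        out = out.merge(lab, on=["participant", "trial"], how="left")
    return out
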