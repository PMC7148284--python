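"""Synthetic ballistic joystick trajectories on the 85 Hz sampling grid.

A trial's movement is a single ballistic push from the neutral position to
near-full deflection along one cardinal direction: radial position follows a
raised-cosine (smooth-step) profile, which gives a bell-shaped speed curve
with a single velocity peak.  The movement is placed in time so that the
radial position crosses the 20% movement radius at the requested RT, and the
trajectory ends in a plateau of identical samples outside that radius so the
experiment's stopping rule (four unchanged samples outside the 20% radius)
fires.  Samples are quantized to 4 decimals, emulating device precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd

from .design import DIRECTION_ANGLES

SAMPLE_RATE = 85.0
MOVEMENT_RADIUS = 0.2
QUANT_DECIMALS = 4


@dataclass
class Trajectory:
    """Per-trial ordered joystick samples in normalized device units."""

    participant_id: int
    trial_id: int
    t: np.ndarray  # seconds, strictly increasing at 1/rate spacing
    x: np.ndarray  # [-1, 1]
    y: np.ndarray  # [-1, 1]
    rate: float = SAMPLE_RATE

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.size < 5:
            raise ValueError("a trajectory needs at least 5 samples")
        if not (np.all(np.diff(self.t) > 0)):
            raise ValueError("trajectory timestamps must be strictly increasing")
        if np.max(np.abs(self.x)) > 1.0 + 1e-9 or np.max(np.abs(self.y)) > 1.0 + 1e-9:
            raise ValueError("joystick deflections must lie in [-1, 1]")

    @property
    def radial(self) -> np.ndarray:
        return np.hypot(self.x, self.y)

    def __len__(self) -> int:
        return self.t.size


def synth_trajectory(
    direction: str,
    rt: float,
    stop_time: float,
    peak_speed: float = 8.0,
    amplitude: float = 1.0,
    angle_jitter: float = 0.0,
    participant_id: int = 0,
    trial_id: int = 0,
) -> Trajectory:
    """Build one ballistic trajectory crossing the 20% radius at ``rt``.

    ``peak_speed`` is the maximum radial speed (normalized units/s) of the
    raised-cosine profile, ``amplitude`` the final radial deflection, and
    ``angle_jitter`` an angular offset (degrees, |jitter| < 45) from the
    cardinal direction.  Raises if the crossing plus the four-sample stop
    plateau cannot be represented on the 85 Hz grid.
    """
    if direction not in DIRECTION_ANGLES:
        raise ValueError(f"unknown direction {direction!r}")
    if not (0.0 < rt < stop_time):
        raise ValueError(f"need 0 < rt < stop_time, got rt={rt}, stop_time={stop_time}")
    if peak_speed <= 0:
        raise ValueError("peak_speed must be > 0")
    if not MOVEMENT_RADIUS < amplitude <= 1.0:
        raise ValueError(f"amplitude must be in ({MOVEMENT_RADIUS}, 1], got {amplitude}")
    if abs(angle_jitter) >= 45.0:
        raise ValueError("angle_jitter must stay within the cardinal sector")

    dt = 1.0 / SAMPLE_RATE
    # raised-cosine radial profile r(tau) = A (1 - cos(pi tau / D)) / 2
    duration = amplitude * math.pi / (2.0 * peak_speed)
    # time offset at which the profile crosses the movement radius
    tau_cross = duration / math.pi * math.acos(1.0 - 2.0 * MOVEMENT_RADIUS / amplitude)
    onset = rt - tau_cross
    end = onset + duration
    n = int(round(stop_time * SAMPLE_RATE)) + 1
    if onset < 0:
        raise ValueError(
            f"rt={rt} is not representable: movement would need to start before t=0 "
            f"(crossing offset {tau_cross:.4f} s at peak_speed={peak_speed})"
        )
    if end > stop_time - 4.0 * dt:
        raise ValueError(
            f"stop_time={stop_time} is not representable on the 85 Hz grid: fewer than "
            "four plateau samples would remain after the movement ends"
        )

    t = np.arange(n) * dt
    tau = np.clip(t - onset + 1e-9, 0.0, duration)
    r = amplitude * 0.5 * (1.0 - np.cos(np.pi * tau / duration))
    ang = math.radians(DIRECTION_ANGLES[direction] + angle_jitter)
    x = np.round(r * math.cos(ang), QUANT_DECIMALS)
    y = np.round(r * math.sin(ang), QUANT_DECIMALS)
    return Trajectory(participant_id, trial_id, t, x, y)


#: default peak radial speeds (units/s) per movement direction; directions
#: differ on purpose — upper-limb ergonomics make some pushes faster
DEFAULT_PEAK_SPEEDS = {"right": 9.5, "up": 8.5, "left": 9.0, "down": 8.0}


def synth_trajectories_for_trials(
    trials: pd.DataFrame,
    seed: int = 0,
    peak_speeds: dict | None = None,
    amplitude_range: tuple = (0.97, 1.0),
    angle_jitter_sd: float = 5.0,
) -> list[Trajectory]:
    """One ballistic trajectory per joystick trial of a trial table.

    Each trajectory crosses the movement radius at the trial's recorded RT
    and pushes toward the trial's *response* direction with a
    direction-dependent peak speed, a near-full final deflection, and a small
    angular jitter (clipped inside the cardinal sector).
    """
    rng = np.random.default_rng(seed)
    speeds = peak_speeds or DEFAULT_PEAK_SPEEDS
    out = []
    joy = trials[trials["session"] == "joystick"].sort_values(["participant", "trial"])
    for row in joy.itertuples():
        ps = speeds[row.response] * rng.uniform(0.85, 1.15)
        amp = rng.uniform(*amplitude_range)
        jit = float(np.clip(rng.normal(0.0, angle_jitter_sd), -40.0, 40.0))
        rt = float(row.rt_s)
        dur = amp * np.pi / (2.0 * ps)
        stop = np.ceil((rt + dur + 8.0 / SAMPLE_RATE) * SAMPLE_RATE) / SAMPLE_RATE
        out.append(
            synth_trajectory(
                row.response,
                rt=rt,
                stop_time=float(stop),
                peak_speed=ps,
                amplitude=amp,
                angle_jitter=jit,
                participant_id=int(row.participant),
                trial_id=int(row.trial),
            )
        )
    return out


def trajectories_to_frame(trajs: list[Trajectory]) -> pd.DataFrame:
    """Long-format serialization: participant, trial, t_s, x, y."""
    parts = [
        pd.DataFrame(
            {
                "participant": tr.participant_id,
                "trial": tr.trial_id,
                "t_s": np.round(tr.t, 6),
                "x": np.round(tr.x, QUANT_DECIMALS),
                "y": np.round(tr.y, QUANT_DECIMALS),
            }
        )
        for tr in trajs
    ]
    return pd.concat(parts, ignore_index=True)


def frame_to_trajectories(df: pd.DataFrame, rate: float = SAMPLE_RATE) -> list[Trajectory]:
    out = []
    for (pid, tid), g in df.groupby(["participant", "trial"], sort=True):
        g = g.sort_values("t_s")
        out.append(
            Trajectory(
                int(pid),
                int(tid),
                g["t_s"].to_numpy(),
                g["x"].to_numpy(),
                g["y"].to_numpy(),
                rate=rate,
            )
        )
    return out
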