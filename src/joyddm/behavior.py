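"""Raw behavioral measures: joystick RT, stopping rule, choice classification,
accuracy/RT summaries, and K-S response-consistency statistics.

Joystick conventions follow the recording setup: position sampled at 85 Hz in
normalized device units, RT defined as the first departure from the 20%
movement radius, response registered when the position is unchanged over four
consecutive samples outside that radius, and the choice taken as the cardinal
direction closest to the final position.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .design import DIFFICULTIES, DIRECTIONS, MODALITIES
from .trajectories import MOVEMENT_RADIUS, Trajectory

NO_RESPONSE = float("nan")
RESPONSE_WINDOW_S = 3.0


def joystick_rt(
    traj: Trajectory, stimulus_onset: float = 0.0, radius: float = MOVEMENT_RADIUS
) -> float:
    """RT = time the joystick first leaves ``radius``, minus stimulus onset.

    Returns NaN (no-response marker) if the radius is never exceeded.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    r = traj.radial
    idx = np.flatnonzero(r > radius)
    if idx.size == 0:
        return NO_RESPONSE
    return float(traj.t[idx[0]] - stimulus_onset)


def detect_stop(
    traj: Trajectory, radius: float = MOVEMENT_RADIUS, window: int = 4
) -> Optional[int]:
    """Earliest sample index i such that samples i-window+1..i are identical
    (exact equality at the serialized precision) and outside ``radius``.

    Returns None (no-stop marker) if the rule never fires within the
    response window.
    """
    if len(traj) < window:
        raise ValueError(f"trajectory shorter than the stop window ({window})")
    x, y, r = traj.x, traj.y, traj.radial
    same = (x[1:] == x[:-1]) & (y[1:] == y[:-1])
    for i in range(window - 1, len(traj)):
        if traj.t[i] - traj.t[0] > RESPONSE_WINDOW_S:
            break
        if r[i] > radius and np.all(same[i - window + 1 : i]):
            return i
    return None


def classify_choice(final_position) -> str:
    """Cardinal direction nearest (in angle) to the final joystick position.

    Ties at the exact 45 degree sector boundaries go to the counter-clockwise
    direction.  Raises at the exact origin, where the angle is undefined.
    """
    x, y = float(final_position[0]), float(final_position[1])
    if x == 0.0 and y == 0.0:
        raise ValueError("choice undefined at the origin")
    ang = math.degrees(math.atan2(y, x)) % 360.0
    sector = int(math.floor(((ang - 45.0) % 360.0) / 90.0))  # 0: up .. 3: right
    return ("up", "left", "down", "right")[sector]


def summarize(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-cell accuracy and mean RT, with marginals.

    Returns rows keyed by (session, difficulty, direction) — ``direction``
    "all" marks the difficulty marginal, and (session, "all", "all") the
    session marginal.  Empty cells are absent from the table, not zero.
    """
    if len(trials) == 0:
        raise ValueError("empty trial list")

    def _agg(g: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "n": len(g),
                "accuracy": float(g["correct"].mean()),
                "mean_rt_s": float(g["rt_s"].mean()),
            }
        )

    rows = []
    for keys, g in trials.groupby(["session", "difficulty", "direction"], sort=True):
        rows.append((*keys, *_agg(g)))
    for keys, g in trials.groupby(["session", "difficulty"], sort=True):
        rows.append((*keys, "all", *_agg(g)))
    for key, g in trials.groupby("session", sort=True):
        rows.append((key, "all", "all", *_agg(g)))
    out = pd.DataFrame(
        rows, columns=["session", "difficulty", "direction", "n", "accuracy", "mean_rt_s"]
    )
    out["n"] = out["n"].astype(int)
    return out


def ks_2samp(x, y) -> float:
    """Two-sample Kolmogorov-Smirnov statistic D = sup |ECDF_x - ECDF_y|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("ks_2samp needs non-empty samples")
    return float(stats.ks_2samp(x, y).statistic)


def ks_consistency(trials: pd.DataFrame) -> dict:
    """Between-modality RT-distribution differences, per participant.

    For every participant with both sessions, computes the K-S statistic
    between joystick and keyboard RT distributions in each difficulty,
    separately for correct and incorrect trials; then correlates (Pearson)
    the easy vs difficult statistics across participants, separately by
    correctness.  Participants lacking trials in a cell are excluded from
    that correlation.

    Returns ``{"per_participant": DataFrame, "correlations": {"correct":
    {...}, "incorrect": {...}}}``; a correlation with fewer than 3
    participants is reported as None.
    """
    rows = []
    for pid, g in trials.groupby("participant", sort=True):
        if set(g["session"].unique()) != set(MODALITIES):
            raise ValueError(f"participant {pid} lacks one of the two sessions")
        for diff in DIFFICULTIES:
            for corr in (True, False):
                sub = g[(g["difficulty"] == diff) & (g["correct"] == corr)]
                jx = sub.loc[sub["session"] == "joystick", "rt_s"].to_numpy()
                kb = sub.loc[sub["session"] == "keyboard", "rt_s"].to_numpy()
                d = ks_2samp(jx, kb) if (jx.size and kb.size) else np.nan
                rows.append((pid, diff, "correct" if corr else "incorrect", d))
    per = pd.DataFrame(rows, columns=["participant", "difficulty", "trials", "ks_d"])

    correlations = {}
    for corr in ("correct", "incorrect"):
        wide = per[per["trials"] == corr].pivot(
            index="participant", columns="difficulty", values="ks_d"
        )
        wide = wide.dropna()
        degenerate = len(wide) and (
            wide["easy"].nunique() == 1 or wide["difficult"].nunique() == 1
        )
        if len(wide) >= 3 and not degenerate:
            r, p = stats.pearsonr(wide["easy"], wide["difficult"])
            correlations[corr] = {"r": float(r), "p": float(p), "n": int(len(wide))}
        else:
            correlations[corr] = {"r": None, "p": None, "n": int(len(wide))}
    return {"per_participant": per, "correlations": correlations}
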