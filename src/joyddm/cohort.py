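"""Synthetic behavioral cohorts: DDM-generated choices/RTs over a design.

Group-level parameter defaults reproduce the study conditions of the
joystick/keyboard motion-discrimination experiment: boundary separation,
nondecision time and the across-trial variabilities split by response
modality, and drift rates split by modality x difficulty x direction.
Participant-level parameters are drawn from Normal group distributions
(truncated to the valid DDM domain); each trial's choice and RT come from
the Euler-Maruyama simulator in :mod:`joyddm.ddm`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ddm import DDMParameters, simulate_trials
from .design import DIFFICULTIES, DIRECTIONS, MODALITIES, generate_design

TRIAL_COLUMNS = [
    "participant",
    "session",
    "block",
    "trial",
    "difficulty",
    "direction",
    "response",
    "correct",
    "rt_s",
]

#: group posterior means of the reference fit (per modality; drift rates
#: keyed by (difficulty, direction))
REFERENCE_GROUP_MEANS = {
    "joystick": {
        "a": 1.508,
        "ter": 0.613,
        "sv": 0.992,
        "st": 0.268,
        "v": {
            ("easy", "up"): 1.694,
            ("easy", "down"): 1.765,
            ("easy", "left"): 2.169,
            ("easy", "right"): 2.351,
            ("difficult", "up"): 0.477,
            ("difficult", "down"): 0.144,
            ("difficult", "left"): 0.441,
            ("difficult", "right"): 0.533,
        },
    },
    "keyboard": {
        "a": 1.572,
        "ter": 0.556,
        "sv": 0.916,
        "st": 0.283,
        "v": {
            ("easy", "up"): 1.269,
            ("easy", "down"): 1.454,
            ("easy", "left"): 1.906,
            ("easy", "right"): 2.187,
            ("difficult", "up"): 0.291,
            ("difficult", "down"): 0.202,
            ("difficult", "left"): 0.216,
            ("difficult", "right"): 0.597,
        },
    },
}


@dataclass(frozen=True)
class GroupParameters:
    """Group-level generating distribution for a synthetic cohort.

    ``means[modality]`` holds a/ter/sv/st scalars and a ``v`` dict keyed by
    (difficulty, direction).  The between-participant SDs apply to a, ter and
    every drift cell; sv and st act at the group level only.
    """

    means: dict = field(default_factory=lambda: REFERENCE_GROUP_MEANS)
    a_sd: float = 0.15
    ter_sd: float = 0.08
    v_sd: float = 0.35

    def shared_across_modalities(self) -> "GroupParameters":
        """Average the two modality columns so both sessions share one
        generating parameter set (the equivalence-testing null)."""
        avg = {}
        for m in MODALITIES:
            avg[m] = {
                k: (self.means["joystick"][k] + self.means["keyboard"][k]) / 2.0
                for k in ("a", "ter", "sv", "st")
            }
            avg[m]["v"] = {
                cell: (self.means["joystick"]["v"][cell] + self.means["keyboard"]["v"][cell]) / 2.0
                for cell in self.means["joystick"]["v"]
            }
        return replace(self, means=avg)


def draw_participant_params(
    group: GroupParameters, n_participants: int, rng: np.random.Generator
) -> dict:
    """Sample per-participant DDM parameters from the group distributions.

    Returns ``{(pid, modality): {"a":..., "ter":..., "sv":..., "st":...,
    "v": {(difficulty, direction): ...}}}`` for pid in 1..n.  Draws violating
    the DDM domain (a <= 0, ter < st/2) are redrawn.
    """
    out = {}
    for pid in range(1, n_participants + 1):
        for m in MODALITIES:
            g = group.means[m]
            a = _redraw_until(rng, g["a"], group.a_sd, lambda x: x > 0.05)
            ter = _redraw_until(rng, g["ter"], group.ter_sd, lambda x: x > g["st"] / 2.0)
            v = {cell: rng.normal(mu, group.v_sd) for cell, mu in g["v"].items()}
            out[(pid, m)] = {"a": a, "ter": ter, "sv": g["sv"], "st": g["st"], "v": v}
    return out


def _redraw_until(rng, mu, sd, ok, max_tries=1000):
    for _ in range(max_tries):
        x = rng.normal(mu, sd)
        if ok(x):
            return x
    raise RuntimeError("could not draw a valid participant parameter")


def simulate_dataset(
    design: pd.DataFrame,
    group_params: GroupParameters | None = None,
    seed: int = 0,
    dt: float = 5e-4,
    participant_params: dict | None = None,
) -> pd.DataFrame:
    """Simulate one TrialRecord row per design row.

    RT = first-passage time + nondecision sample; ``correct`` is True when
    the walk hits the upper boundary, in which case the recorded response
    equals the stimulus direction (an incorrect response is assigned
    uniformly to one of the three remaining directions).  RTs are clipped to
    the 3 s response window by resimulation of timed-out trials at the prior
    mean (timeouts are rare under the reference parameters, < 1%).
    """
    rng = np.random.default_rng(seed)
    group = group_params or GroupParameters()
    pp = participant_params or draw_participant_params(
        group, int(design["participant"].max()), rng
    )

    recs = []
    for (pid, session, diff, dirn), g in design.groupby(
        ["participant", "session", "difficulty", "direction"], sort=True
    ):
        par = pp[(pid, session)]
        params = DDMParameters(
            a=par["a"],
            v=par["v"][(diff, dirn)],
            z=0.5,
            ter=par["ter"],
            sv=par["sv"],
            st=par["st"],
        )
        n = len(g)
        upper, rt, trunc = simulate_trials(params, n, dt=dt, seed=rng)
        # responses outside the 3 s window: redraw once, then clip
        over = (rt > 3.0) | trunc
        if np.any(over):
            u2, rt2, tr2 = simulate_trials(params, int(over.sum()), dt=dt, seed=rng)
            upper[over], rt[over] = u2, rt2
            rt = np.minimum(rt, 3.0 - 1e-4)
        others = [d for d in DIRECTIONS if d != dirn]
        resp = np.where(upper, dirn, rng.choice(others, size=n))
        for row, u, r, rp in zip(g.itertuples(), upper, rt, resp):
            recs.append(
                (pid, session, row.block, row.trial, diff, dirn, rp, bool(u), round(float(r), 4))
            )
    out = pd.DataFrame(recs, columns=TRIAL_COLUMNS)
    return out.sort_values(["participant", "session", "trial"]).reset_index(drop=True)


def synth_cohort(
    n_participants: int = 21,
    seed: int = 0,
    n_blocks: int = 8,
    reps_per_cell: int = 15,
    group_params: GroupParameters | None = None,
    dt: float = 5e-4,
):
    """Design + behavior in one call; returns (design, trials, participant_params)."""
    design = generate_design(n_participants, seed=seed, n_blocks=n_blocks, reps_per_cell=reps_per_cell)
    rng = np.random.default_rng(seed + 1)
    group = group_params or GroupParameters()
    pp = draw_participant_params(group, n_participants, rng)
    trials = simulate_dataset(design, group, seed=seed + 2, dt=dt, participant_params=pp)
    return design, trials, pp


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    df["correct"] = df["correct"].astype(bool)
    return df
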