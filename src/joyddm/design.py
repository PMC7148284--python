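"""Experimental design generator for the four-alternative motion task.

Each participant completes two sessions (joystick, keyboard) of 960 trials in
8 blocks of 120; every block holds 15 repetitions of each of the 8
(direction x difficulty) cells, pseudo-randomized so that no identical
(direction, difficulty) pair occurs in four consecutive trials.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MODALITIES = ("joystick", "keyboard")
DIFFICULTIES = ("easy", "difficult")
DIRECTIONS = ("right", "up", "left", "down")
#: cardinal angle of each direction, degrees
DIRECTION_ANGLES = {"right": 0.0, "up": 90.0, "left": 180.0, "down": 270.0}
#: motion coherence per difficulty
COHERENCE = {"easy": 0.20, "difficult": 0.10}

DESIGN_COLUMNS = ["participant", "session", "block", "trial", "difficulty", "direction"]


class DesignError(RuntimeError):
    """Raised when the pseudo-randomization constraint cannot be satisfied."""


def _max_run_length(cells: np.ndarray) -> int:
    if cells.size == 0:
        return 0
    change = np.flatnonzero(cells[1:] != cells[:-1])
    bounds = np.concatenate(([0], change + 1, [cells.size]))
    return int(np.max(np.diff(bounds)))


def max_condition_run(df: pd.DataFrame) -> int:
    """Longest run of identical (direction, difficulty) pairs in trial order."""
    cells = (
        df.sort_values("trial")["direction"].astype(str) + "|" + df["difficulty"].astype(str)
    ).to_numpy()
    return _max_run_length(cells)


def _shuffle_block(rng: np.random.Generator, reps: int, tail: np.ndarray, max_tries: int):
    """One block of reps x 8 cells with no 4-run, also across the block junction."""
    cells = np.repeat(np.arange(8), reps)
    for _ in range(max_tries):
        perm = rng.permutation(cells)
        seq = np.concatenate([tail, perm])
        if _max_run_length(seq) <= 3:
            return perm
    raise DesignError(
        "could not satisfy the no-4-consecutive constraint "
        f"after {max_tries} reshuffles (generator bug)"
    )


def generate_design(
    n_participants: int,
    seed: int,
    n_blocks: int = 8,
    reps_per_cell: int = 15,
    max_tries: int = 2000,
) -> pd.DataFrame:
    """Generate the full pseudo-randomized design table.

    Returns one row per trial with columns
    ``participant, session, block, trial, difficulty, direction``; both
    sessions are present for every participant and the table is deterministic
    given ``seed``.  ``n_blocks``/``reps_per_cell`` default to the full-scale
    session (8 x 120 = 960 trials); smaller values give reduced designs with
    the same balance invariants per block.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(1, n_participants + 1):
        for session in MODALITIES:
            tail = np.empty(0, dtype=int)
            trial = 0
            for block in range(1, n_blocks + 1):
                perm = _shuffle_block(rng, reps_per_cell, tail, max_tries)
                tail = perm[-3:]
                for cell in perm:
                    trial += 1
                    rows.append(
                        (
                            pid,
                            session,
                            block,
                            trial,
                            DIFFICULTIES[cell // 4],
                            DIRECTIONS[cell % 4],
                        )
                    )
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)
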