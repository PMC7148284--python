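"""Random-dot kinematogram generator (three interleaved dot sequences).

The stimulus is a field of dots inside a circular aperture.  Coherent motion
is introduced by interleaving three uncorrelated dot-position sequences
across frames: in frame t, a fixed proportion of dots (the coherence) is
displaced along the motion direction relative to its position in frame t-3;
the rest are replotted uniformly at random.  Signal dots live for at most
three displacements, after which they are reassigned to random positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import DIRECTION_ANGLES


@dataclass(frozen=True)
class RDKGeometry:
    """Stimulus geometry; defaults match a 14.22 deg aperture at 85 Hz with
    27.77 dots/deg^2/s density and 51.195 deg/s coherent velocity."""

    aperture_diameter: float = 14.22  # degrees of visual angle
    dot_density: float = 27.77  # dots / deg^2 / s
    dot_size: float = 0.14  # degrees
    speed: float = 51.195  # deg / s
    refresh: float = 85.0  # Hz
    interleave: int = 3  # frames between paired sequences
    max_lifetime: int = 3  # signal displacements before reassignment

    def __post_init__(self) -> None:
        if self.aperture_diameter <= 0:
            raise ValueError("aperture_diameter must be > 0")
        if self.refresh <= 0:
            raise ValueError("refresh must be > 0")
        if self.interleave < 1:
            raise ValueError("interleave must be >= 1")
        if self.dots_per_frame < 1:
            raise ValueError("geometry implies < 1 dot per frame")

    @property
    def aperture_radius(self) -> float:
        return self.aperture_diameter / 2.0

    @property
    def dots_per_frame(self) -> int:
        """Density convention: count = density * aperture area / refresh."""
        area = np.pi * self.aperture_radius**2
        return int(round(self.dot_density * area / self.refresh))

    @property
    def step_per_interleave(self) -> float:
        """Coherent displacement (deg) between paired frames (t-3 -> t)."""
        return self.speed * self.interleave / self.refresh


@dataclass
class RDKFrame:
    frame_index: int
    dot_positions: np.ndarray  # (n, 2) degrees relative to aperture center
    signal_flags: np.ndarray = field(default=None)  # (n,) bool


def _uniform_in_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def rdk_frames(
    coherence: float,
    direction: str,
    n_frames: int,
    geometry: RDKGeometry | None = None,
    seed: int = 0,
) -> list[RDKFrame]:
    """Generate ``n_frames`` of dot positions with the given motion coherence.

    Exactly ``round(coherence * dots_per_frame)`` dots per frame carry the
    signal flag.  From frame ``interleave`` onward, flagged dots are displaced
    by ``speed * interleave / refresh`` degrees along ``direction`` relative
    to their position ``interleave`` frames earlier; dots displaced outside
    the aperture wrap to a random interior position; signal identities are
    reassigned after ``max_lifetime`` displacements.
    """
    if not 0.0 <= coherence <= 1.0:
        raise ValueError(f"coherence must be in [0, 1], got {coherence}")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    geom = geometry or RDKGeometry()
    if direction not in DIRECTION_ANGLES:
        raise ValueError(f"unknown direction {direction!r}")
    rng = np.random.default_rng(seed)

    n_dots = geom.dots_per_frame
    n_signal = int(round(coherence * n_dots))
    ang = np.deg2rad(DIRECTION_ANGLES[direction])
    step = geom.step_per_interleave * np.array([np.cos(ang), np.sin(ang)])
    radius = geom.aperture_radius

    frames: list[RDKFrame] = []
    # per interleaved sequence: positions, signal flags, remaining lifetimes
    for i in range(n_frames):
        if i < geom.interleave:
            pos = _uniform_in_disc(rng, n_dots, radius)
            sig = np.zeros(n_dots, dtype=bool)
            sig[rng.choice(n_dots, size=n_signal, replace=False)] = True
            life = np.where(sig, geom.max_lifetime, 0)
        else:
            prev = frames[i - geom.interleave]
            pos = prev.dot_positions.copy()
            sig = prev.signal_flags.copy()
            life = prev._lifetimes.copy()
            # expire signal dots that used up their lifetime
            expired = sig & (life <= 0)
            if np.any(expired):
                sig[expired] = False
                pos[expired] = _uniform_in_disc(rng, int(expired.sum()), radius)
            # top signal set back up to the exact per-frame count
            deficit = n_signal - int(sig.sum())
            if deficit > 0:
                cand = np.flatnonzero(~sig)
                pick = rng.choice(cand, size=deficit, replace=False)
                sig[pick] = True
                life[pick] = geom.max_lifetime
            # displace signal dots; re-randomize noise dots
            pos[sig] = pos[sig] + step
            life[sig] -= 1
            out = sig & (np.hypot(pos[:, 0], pos[:, 1]) > radius)
            if np.any(out):
                pos[out] = _uniform_in_disc(rng, int(out.sum()), radius)
            noise = ~sig
            pos[noise] = _uniform_in_disc(rng, int(noise.sum()), radius)
        frame = RDKFrame(frame_index=i, dot_positions=pos, signal_flags=sig)
        frame._lifetimes = life
        frames.append(frame)
    return frames
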