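"""Bayesian equivalence testing on MCMC chains: HDI, empirical ROPE, P_P|D.

To compare a parameter between two conditions, the index-paired difference
of the two posterior chains is formed and its 95% highest density interval
computed.  The region of practical equivalence (ROPE) is derived empirically
from the chains themselves: within each condition's chain, the difference
between odd- and even-position samples is a draw of "the same parameter
minus itself", so its 95% HDI brackets differences attributable to sampling
alone; the ROPE is the union (widest bounds) of the two single-chain HDIs.
The Bayesian P value P_P|D is the proportion of the difference HDI that
falls inside the ROPE: 1 when the HDI lies entirely within the ROPE, 0 when
they are disjoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Interval",
    "EquivalenceResult",
    "hdi",
    "difference_distribution",
    "rope_from_chains",
    "p_pd",
    "equivalence_test",
]


@dataclass(frozen=True)
class Interval:
    lower: float
    upper: float
    mass: float = 0.95

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(f"invalid interval [{self.lower}, {self.upper}]")
        if not 0.0 < self.mass < 1.0:
            raise ValueError(f"interval mass must be in (0, 1), got {self.mass}")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper


@dataclass(frozen=True)
class EquivalenceResult:
    label: str
    hdi_diff: Interval
    rope: Interval
    p_pd: float

    def to_dict(self) -> dict:
        return {
            "contrast": self.label,
            "hdi_lower": self.hdi_diff.lower,
            "hdi_upper": self.hdi_diff.upper,
            "rope_lower": self.rope.lower,
            "rope_upper": self.rope.upper,
            "p_pd": self.p_pd,
        }


def hdi(samples, mass: float = 0.95) -> Interval:
    """Shortest contiguous interval containing ``ceil(mass * n)`` sorted
    samples (the sample HDI of a unimodal posterior)."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 100:
        raise ValueError(f"hdi needs >= 100 samples, got {n}")
    k = int(np.ceil(mass * n))
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return Interval(float(x[i]), float(x[i + k - 1]), mass)


def difference_distribution(chain_a, chain_b) -> np.ndarray:
    """Index-paired differences a_i - b_i of two equally long chains."""
    a = np.asarray(chain_a, dtype=float)
    b = np.asarray(chain_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"chain length mismatch: {a.shape} vs {b.shape}")
    return a - b


def _odd_even_differences(chain: np.ndarray) -> np.ndarray:
    """Index-paired odd-minus-even sample differences (s1-s2, s3-s4, ...)."""
    c = np.asarray(chain, dtype=float)
    if c.size % 2:
        warnings.warn("odd chain length: trimming the last sample", stacklevel=3)
        c = c[:-1]
    if c.size < 200:
        raise ValueError(f"rope_from_chains needs >= 200 usable chain samples, got {c.size}")
    return c[0::2] - c[1::2]


def rope_from_chains(chain_a, chain_b, mass: float = 0.95) -> Interval:
    """Empirical ROPE: widest bounds of the two single-chain odd/even HDIs."""
    ha = hdi(_odd_even_differences(chain_a), mass)
    hb = hdi(_odd_even_differences(chain_b), mass)
    return Interval(min(ha.lower, hb.lower), max(ha.upper, hb.upper), mass)


def p_pd(hdi_diff: Interval, rope: Interval) -> float:
    """Proportion of the difference HDI lying inside the ROPE.

    0 when the intervals are disjoint; 1 when the HDI is contained in the
    ROPE.  A zero-width HDI degenerates to a membership indicator.
    """
    if hdi_diff.width == 0.0:
        return 1.0 if rope.contains(hdi_diff.lower) else 0.0
    overlap = min(hdi_diff.upper, rope.upper) - max(hdi_diff.lower, rope.lower)
    return float(np.clip(overlap / hdi_diff.width, 0.0, 1.0))


def equivalence_test(chain_a, chain_b, label: str = "", mass: float = 0.95) -> EquivalenceResult:
    """HDI of the paired difference, empirical ROPE, and P_P|D for one contrast."""
    diff = difference_distribution(chain_a, chain_b)
    h = hdi(diff, mass)
    r = rope_from_chains(chain_a, chain_b, mass)
    return EquivalenceResult(label=label, hdi_diff=h, rope=r, p_pd=p_pd(h, r))
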