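"""Two-boundary drift-diffusion model: first-passage density, simulator, likelihood.

The model: noisy evidence X(t) starts at ``z * a`` and diffuses with drift ``v``
and unit within-trial noise (sigma = 1 scaling) between an upper boundary at
``a`` (correct response) and a lower boundary at 0 (incorrect response).  The
observed response time is the boundary-crossing (decision) time plus a
nondecision latency ``Ter``.  Two across-trial variabilities are supported:
the trial-wise drift is Normal(v, sv) and the trial-wise nondecision time is
Uniform(Ter - st/2, Ter + st/2).

The first-passage density uses the classical pair of infinite-series
expansions of the Wiener FPT distribution — a small-time expansion (sum over
image charges) and a large-time expansion (sine series) — with the truncation
length chosen adaptively from the requested error tolerance, switching to
whichever series needs fewer terms.  Drift variability ``sv`` is integrated
out analytically (the drift enters the density only through a Gaussian
factor); nondecision variability ``st`` is integrated by fixed-order
Gauss-Legendre quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss

__all__ = [
    "DDMParameters",
    "wfpt_pdf",
    "simulate_trial",
    "simulate_trials",
    "log_likelihood",
    "decision_time_cdf",
]

_GL_ORDER = 10
_GL_X, _GL_W = leggauss(_GL_ORDER)

#: hard cap on simulated decision time (seconds); slower walks are truncated
SIM_TIME_CAP = 10.0


@dataclass(frozen=True)
class DDMParameters:
    """Diffusion-model parameters for one participant x condition cell.

    a : boundary separation (evidence units, > 0)
    v : mean drift rate (evidence/s); positive drifts toward the upper
        (correct) boundary
    z : relative start point in (0, 1); 0.5 = unbiased
    ter : mean nondecision time (s)
    sv : SD of the trial-wise Normal drift variability (>= 0)
    st : range of the trial-wise Uniform nondecision variability (s, >= 0)
    """

    a: float
    v: float
    z: float = 0.5
    ter: float = 0.0
    sv: float = 0.0
    st: float = 0.0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"boundary separation a must be > 0, got {self.a}")
        if not 0 < self.z < 1:
            raise ValueError(f"relative start point z must be in (0, 1), got {self.z}")
        if self.sv < 0:
            raise ValueError(f"drift variability sv must be >= 0, got {self.sv}")
        if self.st < 0:
            raise ValueError(f"nondecision range st must be >= 0, got {self.st}")
        if self.ter - self.st / 2.0 < 0:
            raise ValueError(
                f"nondecision window extends below zero: ter={self.ter}, st={self.st}"
            )


def _series_density(tt: np.ndarray, w: np.ndarray, err_tol: float) -> np.ndarray:
    """Density of the *normalized* FPT problem (a=1, v=0) at the lower boundary.

    ``tt`` is decision time divided by a**2; ``w`` the relative start point.
    Chooses per element between the small-time and large-time series using the
    standard truncation-count criterion.
    """
    tt = np.asarray(tt, dtype=float)
    w = np.broadcast_to(np.asarray(w, dtype=float), tt.shape)
    out = np.zeros(tt.shape, dtype=float)
    pos = tt > 0
    if not np.any(pos):
        return out
    t = tt[pos]
    ww = w[pos]

    # number of terms needed by each series for truncation error < err_tol
    with np.errstate(divide="ignore", invalid="ignore"):
        fine = 2.0 * np.sqrt(2.0 * np.pi * t) * err_tol < 1.0
        ks = np.where(
            fine,
            2.0 + np.sqrt(np.maximum(-2.0 * t * np.log(2.0 * np.sqrt(2.0 * np.pi * t) * err_tol), 0.0)),
            2.0,
        )
        ks = np.maximum(ks, np.sqrt(t) + 1.0)
        kl = np.where(
            fine,
            np.sqrt(np.maximum(-2.0 * np.log(np.pi * t * err_tol), 0.0) / (np.pi**2 * t)),
            1.0 / (np.pi * np.sqrt(t)),
        )
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(t)))

    use_small = ks < kl
    dens = np.empty_like(t)

    if np.any(use_small):
        ts, ws_ = t[use_small], ww[use_small]
        K = int(np.ceil(ks[use_small].max()))
        k_lo = -((K - 1) // 2)
        k_hi = (K - 1) // 2 + (K - 1) % 2
        kk = np.arange(k_lo, k_hi + 1, dtype=float)
        arg = ws_[:, None] + 2.0 * kk[None, :]
        s = np.sum(arg * np.exp(-(arg**2) / (2.0 * ts[:, None])), axis=1)
        dens[use_small] = s / np.sqrt(2.0 * np.pi * ts**3)

    use_large = ~use_small
    if np.any(use_large):
        tl, wl = t[use_large], ww[use_large]
        K = int(np.ceil(kl[use_large].max()))
        kk = np.arange(1, K + 1, dtype=float)
        s = np.sum(
            kk[None, :]
            * np.exp(-(kk[None, :] ** 2) * np.pi**2 * tl[:, None] / 2.0)
            * np.sin(kk[None, :] * np.pi * wl[:, None]),
            axis=1,
        )
        dens[use_large] = np.pi * s

    out[pos] = np.maximum(dens, 0.0)
    return out


def wfpt_density_array(
    t: np.ndarray,
    v: np.ndarray,
    a: np.ndarray,
    w: np.ndarray,
    sv: np.ndarray | float = 0.0,
    err_tol: float = 1e-7,
) -> np.ndarray:
    """Vectorized lower-boundary FPT density with analytic sv integration.

    ``t`` is decision time (nondecision already removed).  All arguments
    broadcast.  Upper-boundary densities follow by the reflection
    ``f_upper(t | v, w) = f_lower(t | -v, 1 - w)``.
    """
    t = np.asarray(t, dtype=float)
    v, a, w, sv = (np.broadcast_to(np.asarray(x, dtype=float), t.shape) for x in (v, a, w, sv))
    tpos = np.where(t > 0, t, 1.0)
    base = _series_density(np.where(t > 0, tpos / a**2, -1.0), w, err_tol)
    # Gaussian drift factor, integrated over trial drift ~ Normal(v, sv)
    denom = 1.0 + sv**2 * tpos
    expo = (sv**2 * a**2 * w**2 - 2.0 * v * a * w - v**2 * tpos) / (2.0 * denom)
    fac = np.exp(np.minimum(expo, 700.0)) / np.sqrt(denom)
    return np.where(t > 0, base * fac / a**2, 0.0)


def wfpt_pdf(
    t,
    params: DDMParameters,
    boundary: str = "upper",
    err_tol: float = 1e-7,
) -> np.ndarray | float:
    """First-passage density of the decision time at one boundary.

    ``t`` is the decision time in seconds (nondecision time already removed);
    ``boundary`` is ``"upper"`` (correct) or ``"lower"`` (incorrect).  Returns
    0 for t <= 0.  Includes the sv mixture if ``params.sv > 0``; the st
    mixture applies to observed RTs and lives in :func:`log_likelihood`.
    """
    if err_tol <= 0:
        raise ValueError("err_tol must be > 0")
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if boundary == "upper":
        v_eff, w_eff = -params.v, 1.0 - params.z
    else:
        v_eff, w_eff = params.v, params.z
    out = wfpt_density_array(t_arr, v_eff, params.a, w_eff, params.sv, err_tol)
    return out if np.ndim(t) else float(out[0])


def decision_time_cdf(
    params: DDMParameters,
    t_grid: np.ndarray,
    boundary: str | None = None,
    err_tol: float = 1e-9,
) -> np.ndarray:
    """Cumulative first-passage distribution on ``t_grid`` by trapezoid rule.

    ``boundary=None`` returns the marginal decision-time CDF (both boundaries
    pooled), which integrates to 1.
    """
    from scipy.integrate import cumulative_trapezoid

    t_grid = np.asarray(t_grid, dtype=float)
    if boundary is None:
        dens = wfpt_pdf(t_grid, params, "upper", err_tol) + wfpt_pdf(
            t_grid, params, "lower", err_tol
        )
    else:
        dens = wfpt_pdf(t_grid, params, boundary, err_tol)
    return cumulative_trapezoid(dens, t_grid, initial=0.0)


def simulate_trials(
    params: DDMParameters,
    n: int,
    dt: float = 1e-4,
    seed: int | np.random.Generator = 0,
    block: int = 400,
):
    """Euler-Maruyama simulation of ``n`` trials.

    Returns ``(upper, rt, truncated)``: boolean upper-boundary flags, observed
    RTs (decision time + nondecision sample) and truncation flags for walks
    exceeding the 10 s cap.  The walk steps are ``v*dt + sqrt(dt)*N(0,1)``
    with per-trial drift drawn from Normal(v, sv).
    """
    if dt > 1e-3:
        raise ValueError(f"simulation step dt must be <= 1e-3 s, got {dt}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    drift = rng.normal(params.v, params.sv, size=n) if params.sv > 0 else np.full(n, params.v)
    x = np.full(n, params.z * params.a)
    steps = np.zeros(n, dtype=np.int64)
    upper = np.zeros(n, dtype=bool)
    done = np.zeros(n, dtype=bool)
    active = np.arange(n)
    max_steps = int(round(SIM_TIME_CAP / dt))
    sdt = math.sqrt(dt)
    elapsed = 0

    while active.size and elapsed < max_steps:
        k = min(block, max_steps - elapsed)
        inc = drift[active, None] * dt + sdt * rng.standard_normal((active.size, k))
        path = x[active, None] + np.cumsum(inc, axis=1)
        hit_up = path >= params.a
        hit_lo = path <= 0.0
        hit = hit_up | hit_lo
        any_hit = hit.any(axis=1)
        first = np.argmax(hit, axis=1)
        idx_hit = active[any_hit]
        f = first[any_hit]
        steps[idx_hit] = elapsed + f + 1
        upper[idx_hit] = hit_up[any_hit, f]
        done[idx_hit] = True
        keep = ~any_hit
        x[active[keep]] = path[keep, -1]
        active = active[keep]
        elapsed += k

    truncated = ~done
    steps[truncated] = max_steps
    tnd = params.ter + (
        rng.uniform(-params.st / 2.0, params.st / 2.0, size=n) if params.st > 0 else 0.0
    )
    rt = steps * dt + tnd
    return upper, rt, truncated


def simulate_trials_mixed(
    a: np.ndarray,
    v: np.ndarray,
    ter: np.ndarray,
    sv: np.ndarray,
    st: np.ndarray,
    z: float = 0.5,
    dt: float = 1e-3,
    seed: int | np.random.Generator = 0,
    block: int = 200,
):
    """Euler-Maruyama simulation with per-trial parameter arrays.

    Same walk as :func:`simulate_trials` but every trial may carry its own
    parameters (used for posterior-predictive simulation, where each trial
    belongs to a different participant x condition cell).
    """
    if dt > 1e-3:
        raise ValueError(f"simulation step dt must be <= 1e-3 s, got {dt}")
    a, v, ter, sv, st = (np.asarray(x, dtype=float) for x in (a, v, ter, sv, st))
    n = a.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    drift = rng.normal(v, np.maximum(sv, 0.0))
    x = np.full(n, z) * a
    steps = np.zeros(n, dtype=np.int64)
    upper = np.zeros(n, dtype=bool)
    done = np.zeros(n, dtype=bool)
    active = np.arange(n)
    max_steps = int(round(SIM_TIME_CAP / dt))
    sdt = math.sqrt(dt)
    elapsed = 0
    while active.size and elapsed < max_steps:
        k = min(block, max_steps - elapsed)
        inc = drift[active, None] * dt + sdt * rng.standard_normal((active.size, k))
        path = x[active, None] + np.cumsum(inc, axis=1)
        hit_up = path >= a[active, None]
        hit_lo = path <= 0.0
        hit = hit_up | hit_lo
        any_hit = hit.any(axis=1)
        first = np.argmax(hit, axis=1)
        idx_hit = active[any_hit]
        f = first[any_hit]
        steps[idx_hit] = elapsed + f + 1
        upper[idx_hit] = hit_up[any_hit, f]
        done[idx_hit] = True
        keep = ~any_hit
        x[active[keep]] = path[keep, -1]
        active = active[keep]
        elapsed += k
    truncated = ~done
    steps[truncated] = max_steps
    tnd = ter + rng.uniform(-0.5, 0.5, size=n) * st
    rt = steps * dt + tnd
    return upper, rt, truncated


def simulate_trial(params: DDMParameters, dt: float = 1e-4, seed: int = 0):
    """Simulate a single trial; returns ``(boundary, rt)`` with boundary in
    {"upper", "lower"} (or "truncated" past the 10 s cap)."""
    upper, rt, trunc = simulate_trials(params, 1, dt=dt, seed=seed)
    if trunc[0]:
        return "truncated", float(rt[0])
    return ("upper" if upper[0] else "lower"), float(rt[0])


def _loglik_kernel(
    rt: np.ndarray,
    correct: np.ndarray,
    a: np.ndarray,
    v: np.ndarray,
    ter: np.ndarray,
    sv: np.ndarray,
    st: np.ndarray,
    z: float = 0.5,
    err_tol: float = 1e-7,
) -> np.ndarray:
    """Per-trial log density of observed RTs under the sv/st-mixture DDM.

    All parameter arrays are per trial (broadcast against ``rt``).  Correct
    trials are scored at the upper boundary via the reflection v -> -v,
    w -> 1-z.  The st mixture is a Gauss-Legendre average of the sv-integrated
    density over the nondecision window.  Returns -inf where the RT is
    unreachable.
    """
    rt = np.asarray(rt, dtype=float)
    n = rt.shape[0]
    a, v, ter, sv, st = (np.broadcast_to(np.asarray(x, float), (n,)) for x in (a, v, ter, sv, st))
    correct = np.asarray(correct, dtype=bool)
    v_eff = np.where(correct, -v, v)
    w_eff = np.where(correct, 1.0 - z, z)

    # nondecision nodes: ter + (st/2) * x_j, x_j Gauss-Legendre on [-1, 1]
    tnd = ter[:, None] + 0.5 * st[:, None] * _GL_X[None, :]
    tdec = rt[:, None] - tnd
    dens_nodes = wfpt_density_array(
        tdec,
        v_eff[:, None],
        a[:, None],
        w_eff[:, None],
        sv[:, None],
        err_tol,
    )
    dens = 0.5 * np.sum(_GL_W[None, :] * dens_nodes, axis=1)
    # degenerate st: point evaluation at ter
    no_st = st <= 1e-12
    if np.any(no_st):
        d0 = wfpt_density_array(rt - ter, v_eff, a, w_eff, sv, err_tol)
        dens = np.where(no_st, d0, dens)
    with np.errstate(divide="ignore"):
        return np.where(dens > 0, np.log(np.maximum(dens, 1e-300)), -np.inf)


def log_likelihood(trials, params: DDMParameters, err_tol: float = 1e-7) -> float:
    """Summed log likelihood of a list of trials under one parameter set.

    ``trials`` is a sequence of objects (or a DataFrame) with ``rt`` (seconds)
    and ``correct`` (bool) fields; correct responses are scored at the upper
    boundary, errors at the lower.  An empty list scores 0.  Returns ``-inf``
    if any trial RT is unreachable under ``params``.
    """
    rt, correct = _extract_rt_correct(trials)
    if rt.size == 0:
        return 0.0
    ll = _loglik_kernel(
        rt,
        correct,
        params.a,
        params.v,
        params.ter,
        params.sv,
        params.st,
        z=params.z,
        err_tol=err_tol,
    )
    return float(np.sum(ll))


def _extract_rt_correct(trials):
    import pandas as pd

    if isinstance(trials, pd.DataFrame):
        return trials["rt"].to_numpy(dtype=float), trials["correct"].to_numpy(dtype=bool)
    rt = np.array([t.rt for t in trials], dtype=float)
    correct = np.array([t.correct for t in trials], dtype=bool)
    return rt, correct
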