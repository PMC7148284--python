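"""Hierarchical Bayesian estimation of the drift-diffusion model.

Parameter-sharing structure: boundary separation ``a``, nondecision time
``ter`` and the across-trial variabilities ``sv``/``st`` are split by
response modality; drift rate ``v`` is split by modality x difficulty x
direction (16 cells); the start point ``z`` is fixed at 0.5 and never
sampled — 2 + 2 + 2 + 2 + 16 = 24 group-level means in total.  ``a``,
``ter`` and every drift cell carry a participant level drawn from Normal
group distributions; ``sv`` and ``st`` are modeled at the group level only
(participant-level variabilities are weakly identified at these trial
counts).

Inference is single-chain adaptive Metropolis-within-Gibbs: participant
parameters are updated by Gaussian random-walk proposals with scales adapted
to ~44% acceptance during burn-in (frozen afterwards), group means by exact
conjugate (truncated-)normal Gibbs draws given the participant values, and
group SDs and the group-level sv/st by random-walk Metropolis.  Priors are
weakly informative and documented in ``PRIORS``.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .ddm import _loglik_kernel, simulate_trials_mixed
from .design import DIFFICULTIES, DIRECTIONS, MODALITIES

__all__ = [
    "ModelSpec",
    "PosteriorChains",
    "build_model",
    "sample_posterior",
    "geweke_diagnostic",
    "posterior_predictive",
]

#: prior hyperparameters: group means a ~ N(1.5, 1) truncated > 0,
#: ter ~ N(0.5, 0.5) truncated > 0, v ~ N(0, 5); group-level sv ~ HN(2),
#: st ~ HN(0.5); group SDs ~ HN(1)
PRIORS = {
    "mu_a": (1.5, 1.0),
    "mu_ter": (0.5, 0.5),
    "mu_v": (0.0, 5.0),
    "sv_scale": 2.0,
    "st_scale": 0.5,
    "sigma_scale": 1.0,
}


@dataclass(frozen=True)
class ModelSpec:
    """Factor structure of the hierarchical DDM."""

    modalities: tuple = MODALITIES
    difficulties: tuple = DIFFICULTIES
    directions: tuple = DIRECTIONS
    start_point: float = 0.5
    estimate_start_point: bool = False
    err_tol: float = 1e-7

    @property
    def n_v_cells(self) -> int:
        return len(self.modalities) * len(self.difficulties) * len(self.directions)

    @property
    def n_group_means(self) -> int:
        return 4 * len(self.modalities) + self.n_v_cells

    def v_label(self, cell: int) -> str:
        nm, nd, nr = len(self.modalities), len(self.difficulties), len(self.directions)
        m, rem = divmod(cell, nd * nr)
        d, r = divmod(rem, nr)
        return f"v({self.modalities[m]},{self.difficulties[d]},{self.directions[r]})"

    def hash(self) -> str:
        payload = json.dumps(
            [list(self.modalities), list(self.difficulties), list(self.directions), self.start_point],
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class HierarchicalDDM:
    """Indexed trial data plus the factor structure, ready for sampling."""

    def __init__(self, trials: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        self.participants = sorted(trials["participant"].unique())
        self.P = len(self.participants)
        pmap = {p: i for i, p in enumerate(self.participants)}
        mmap = {m: i for i, m in enumerate(spec.modalities)}
        dmap = {d: i for i, d in enumerate(spec.difficulties)}
        rmap = {r: i for i, r in enumerate(spec.directions)}

        self.rt = trials["rt_s"].to_numpy(dtype=float)
        self.correct = trials["correct"].to_numpy(dtype=bool)
        self.N = self.rt.size
        self.p_idx = trials["participant"].map(pmap).to_numpy(dtype=np.int64)
        self.m_idx = trials["session"].map(mmap).to_numpy(dtype=np.int64)
        nd, nr = len(spec.difficulties), len(spec.directions)
        self.cell16 = (
            self.m_idx * nd * nr
            + trials["difficulty"].map(dmap).to_numpy(dtype=np.int64) * nr
            + trials["direction"].map(rmap).to_numpy(dtype=np.int64)
        )
        self.comp_a = self.p_idx * len(spec.modalities) + self.m_idx
        self.comp_v = self.p_idx * spec.n_v_cells + self.cell16

        # every participant x drift cell must hold data
        counts = np.bincount(self.comp_v, minlength=self.P * spec.n_v_cells)
        empty = np.flatnonzero(counts == 0)
        if empty.size:
            p, cell = divmod(int(empty[0]), spec.n_v_cells)
            raise ValueError(
                f"participant {self.participants[p]} has zero trials in cell "
                f"{spec.v_label(cell)}"
            )

        # per-(participant, modality) minimum RT, for initialization/support
        self.min_rt = np.full((self.P, len(spec.modalities)), np.inf)
        np.minimum.at(self.min_rt, (self.p_idx, self.m_idx), self.rt)


def build_model(trials: pd.DataFrame, spec: ModelSpec | None = None) -> HierarchicalDDM:
    """Index the trial table against the factor structure.

    Rejects specifications asking for a free start point (the design gives
    the participants no response bias to estimate) and trial tables with an
    empty participant x condition cell.
    """
    spec = spec or ModelSpec()
    if spec.estimate_start_point:
        raise ValueError("the start point z is fixed at 0.5 and is never sampled")
    if "rt_s" not in trials.columns:
        trials = trials.rename(columns={"rt": "rt_s"})
    return HierarchicalDDM(trials, spec)


@dataclass
class PosteriorChains:
    """MCMC output: named scalar chains plus provenance."""

    names: list
    chains: np.ndarray  # (n_total, n_params)
    n_total: int
    n_burn: int
    seed: int
    spec: ModelSpec
    acceptance_rates: dict = field(default_factory=dict)
    participants: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self._col = {n: i for i, n in enumerate(self.names)}

    @property
    def n_retained(self) -> int:
        return self.n_total - self.n_burn

    def get(self, name: str) -> np.ndarray:
        """Retained (post-burn-in) samples of one parameter."""
        return self.chains[self.n_burn :, self._col[name]]

    def full(self, name: str) -> np.ndarray:
        return self.chains[:, self._col[name]]

    @property
    def group_mean_names(self) -> list:
        out = []
        for m in self.spec.modalities:
            out += [f"a({m})", f"ter({m})", f"sv({m})", f"st({m})"]
        out += [self.spec.v_label(c) for c in range(self.spec.n_v_cells)]
        return out

    def summary(self) -> pd.DataFrame:
        rows = [
            (n, float(self.get(n).mean()), float(self.get(n).std(ddof=1)))
            for n in self.group_mean_names
        ]
        return pd.DataFrame(rows, columns=["parameter", "mean", "sd"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.chains, columns=self.names)

    def provenance(self) -> dict:
        return {
            "seed": self.seed,
            "n_total": self.n_total,
            "n_burn": self.n_burn,
            "spec_hash": self.spec.hash(),
            "acceptance_rates": self.acceptance_rates,
        }


def _log_normal_pdf(x, mu, sigma):
    return -0.5 * ((x - mu) / sigma) ** 2 - np.log(sigma)


def sample_posterior(
    model: HierarchicalDDM,
    n_total: int = 15_000,
    n_burn: int = 7_000,
    seed: int = 0,
    progress: bool = False,
) -> PosteriorChains:
    """Run the adaptive Metropolis-within-Gibbs sampler.

    Deterministic given ``seed``.  Raises if any proposal family ends with a
    post-adaptation acceptance rate below 1% (a mis-scaled proposal, not a
    valid posterior sample).
    """
    if not n_total > n_burn >= 0:
        raise ValueError("need n_total > n_burn >= 0")
    spec = model.spec
    rng = np.random.default_rng(seed)
    P, M, V = model.P, len(spec.modalities), spec.n_v_cells
    rt, correct = model.rt, model.correct
    p_idx, m_idx = model.p_idx, model.m_idx
    comp_a, comp_v = model.comp_a, model.comp_v
    z = spec.start_point
    err_tol = spec.err_tol

    # --- initialization -------------------------------------------------
    st_g = np.full(M, 0.15)
    sv_g = np.full(M, 0.5)
    th_t = np.maximum(0.7 * model.min_rt, st_g[None, :] / 2 + 1e-3)
    th_a = np.full((P, M), 1.5)
    # crude drift init from per-cell accuracy: P(correct) = 1/(1+exp(-a v))
    acc = np.bincount(comp_v, weights=correct.astype(float), minlength=P * V)
    ncell = np.bincount(comp_v, minlength=P * V)
    accp = np.clip(acc / np.maximum(ncell, 1), 0.1, 0.9)
    th_v = (np.log(accp / (1 - accp)) / 1.5).reshape(P, V)

    mu_a, sg_a = th_a.mean(axis=0), np.full(M, 0.3)
    mu_t, sg_t = th_t.mean(axis=0), np.full(M, 0.15)
    mu_v, sg_v = th_v.mean(axis=0), np.full(V, 0.5)

    def trial_ll(a_pm, t_pm, v_pv, sv_m, st_m):
        return _loglik_kernel(
            rt,
            correct,
            a_pm.reshape(-1)[comp_a],
            v_pv.reshape(-1)[comp_v],
            t_pm.reshape(-1)[comp_a],
            sv_m[m_idx],
            st_m[m_idx],
            z=z,
            err_tol=err_tol,
        )

    cur = trial_ll(th_a, th_t, th_v, sv_g, st_g)
    if not np.all(np.isfinite(cur)):
        # ease nondecision times until every RT is reachable
        bad = ~np.isfinite(cur)
        while np.any(bad):
            st_g *= 0.5
            th_t[:] = np.maximum(0.8 * th_t, st_g.max() / 2 + 1e-3)
            cur = trial_ll(th_a, th_t, th_v, sv_g, st_g)
            bad = ~np.isfinite(cur)

    # proposal scales (log-adapted during burn-in)
    sc_a = np.full((P, M), 0.08)
    sc_t = np.full((P, M), 0.03)
    sc_v = np.full((P, V), 0.25)
    sc_sv = np.full(M, 0.08)
    sc_st = np.full(M, 0.015)
    sc_sg = {"a": np.full(M, 0.3), "ter": np.full(M, 0.3), "v": np.full(V, 0.3)}

    names: list = []
    for m in spec.modalities:
        names += [f"a({m})", f"ter({m})", f"sv({m})", f"st({m})"]
    names += [spec.v_label(c) for c in range(V)]
    for m in spec.modalities:
        names += [f"sigma_a({m})", f"sigma_ter({m})"]
    names += [f"sigma_{spec.v_label(c)}" for c in range(V)]
    for pid in model.participants:
        for m in spec.modalities:
            names += [f"a({m})|p{pid}", f"ter({m})|p{pid}"]
        names += [f"{spec.v_label(c)}|p{pid}" for c in range(V)]
    chains = np.empty((n_total, len(names)))

    acc_ct = {k: 0.0 for k in ("theta_a", "theta_ter", "theta_v", "sv", "st", "sigma")}
    acc_n = {k: 0 for k in acc_ct}

    def _mh_block(theta, scale, mu, sg, which, it):
        """Joint random-walk update of one participant-level family."""
        nonlocal cur
        prop = theta + scale * rng.standard_normal(theta.shape)
        if which == "theta_a":
            valid = prop > 1e-3
            new = trial_ll(prop, th_t, th_v, sv_g, st_g)
            comp = comp_a
        elif which == "theta_ter":
            valid = prop > st_g[None, :] / 2
            new = trial_ll(th_a, prop, th_v, sv_g, st_g)
            comp = comp_a
        else:
            valid = np.ones(prop.shape, dtype=bool)
            new = trial_ll(th_a, th_t, prop, sv_g, st_g)
            comp = comp_v
        with np.errstate(invalid="ignore"):
            d_ll = np.bincount(comp, weights=new - cur, minlength=theta.size)
        d_pr = _log_normal_pdf(prop, mu, sg) - _log_normal_pdf(theta, mu, sg)
        delta = d_ll.reshape(theta.shape) + d_pr
        delta = np.where(valid, delta, -np.inf)
        alpha = np.exp(np.minimum(delta, 0.0))
        accept = rng.uniform(size=theta.shape) < alpha
        theta[accept] = prop[accept]
        cur = np.where(accept.reshape(-1)[comp], new, cur)
        if it < n_burn:
            scale *= np.exp(_gamma(it) * (alpha - 0.44))
        else:
            acc_ct[which] += accept.mean()
            acc_n[which] += 1
        return theta, scale

    def _gamma(it):
        return min(0.25, 2.0 / (1.0 + it) ** 0.6)

    for it in range(n_total):
        th_a, sc_a = _mh_block(th_a, sc_a, mu_a[None, :], sg_a[None, :], "theta_a", it)
        th_t, sc_t = _mh_block(th_t, sc_t, mu_t[None, :], sg_t[None, :], "theta_ter", it)
        th_v, sc_v = _mh_block(th_v, sc_v, mu_v[None, :], sg_v[None, :], "theta_v", it)

        # group-level sv / st (Metropolis over the full modality likelihood)
        for which, vec, sc, prior_scale in (
            ("sv", sv_g, sc_sv, PRIORS["sv_scale"]),
            ("st", st_g, sc_st, PRIORS["st_scale"]),
        ):
            prop = vec + sc * rng.standard_normal(M)
            if which == "sv":
                valid = prop >= 0.0
                new = trial_ll(th_a, th_t, th_v, prop, st_g)
            else:
                valid = (prop >= 0.0) & (prop <= 2.0 * th_t.min(axis=0)) & (prop <= 2.0 * mu_t)
                new = trial_ll(th_a, th_t, th_v, sv_g, prop)
            with np.errstate(invalid="ignore"):
                d_ll = np.bincount(m_idx, weights=new - cur, minlength=M)
            d_pr = (vec**2 - prop**2) / (2.0 * prior_scale**2)
            delta = np.where(valid, d_ll + d_pr, -np.inf)
            alpha = np.exp(np.minimum(delta, 0.0))
            accept = rng.uniform(size=M) < alpha
            vec[accept] = prop[accept]
            cur = np.where(accept[m_idx], new, cur)
            if it < n_burn:
                sc *= np.exp(_gamma(it) * (alpha - 0.44))
            else:
                acc_ct[which] += accept.mean()
                acc_n[which] += 1

        # conjugate group means; a truncated at 0, ter at st/2 (the group-level
        # nondecision window must stay non-negative), v unconstrained
        for theta, mu, sg, prior_key, lower in (
            (th_a, mu_a, sg_a, "mu_a", np.zeros(M)),
            (th_t, mu_t, sg_t, "mu_ter", st_g / 2.0),
            (th_v, mu_v, sg_v, "mu_v", None),
        ):
            m0, s0 = PRIORS[prior_key]
            n_p = theta.shape[0]
            prec = 1.0 / s0**2 + n_p / sg**2
            mhat = (m0 / s0**2 + theta.sum(axis=0) / sg**2) / prec
            sd = 1.0 / np.sqrt(prec)
            if lower is not None:
                lo = (lower - mhat) / sd
                u = rng.uniform(size=mu.shape)
                mu[:] = np.maximum(
                    truncnorm.ppf(u, lo, np.inf, loc=mhat, scale=sd), lower + 1e-12
                )
            else:
                mu[:] = mhat + sd * rng.standard_normal(mu.shape)

        # group SDs: random walk on log sigma with half-normal prior
        sig_acc = 0.0
        for fam, theta, mu, sg in (
            ("a", th_a, mu_a, sg_a),
            ("ter", th_t, mu_t, sg_t),
            ("v", th_v, mu_v, sg_v),
        ):
            sc = sc_sg[fam]
            ls = np.log(sg)
            prop = np.exp(ls + sc * rng.standard_normal(sg.shape))
            ss = ((theta - mu[None, :]) ** 2).sum(axis=0)
            n_p = theta.shape[0]

            def _lp(s):
                return (
                    -n_p * np.log(s)
                    - ss / (2.0 * s**2)
                    - s**2 / (2.0 * PRIORS["sigma_scale"] ** 2)
                    + np.log(s)  # log-scale Jacobian
                )

            delta = _lp(prop) - _lp(sg)
            alpha = np.exp(np.minimum(delta, 0.0))
            accept = rng.uniform(size=sg.shape) < alpha
            sg[accept] = prop[accept]
            if it < n_burn:
                sc *= np.exp(_gamma(it) * (alpha - 0.44))
            sig_acc += accept.mean() / 3.0
        if it >= n_burn:
            acc_ct["sigma"] += sig_acc
            acc_n["sigma"] += 1

        row = []
        for m in range(M):
            row += [mu_a[m], mu_t[m], sv_g[m], st_g[m]]
        row += list(mu_v)
        for m in range(M):
            row += [sg_a[m], sg_t[m]]
        row += list(sg_v)
        for p in range(P):
            for m in range(M):
                row += [th_a[p, m], th_t[p, m]]
            row += list(th_v[p])
        chains[it] = row

        if progress and (it + 1) % 500 == 0:
            print(f"  mcmc {it + 1}/{n_total}", flush=True)

    rates = {k: (acc_ct[k] / acc_n[k] if acc_n[k] else float("nan")) for k in acc_ct}
    low = {k: r for k, r in rates.items() if np.isfinite(r) and r < 0.01}
    if low:
        raise RuntimeError(f"proposal families with acceptance < 1% after adaptation: {low}")

    return PosteriorChains(
        names=names,
        chains=chains,
        n_total=n_total,
        n_burn=n_burn,
        seed=seed,
        spec=spec,
        acceptance_rates=rates,
        participants=list(model.participants),
    )


def _long_run_variance(x: np.ndarray) -> float:
    """Newey-West estimate of the spectral density at frequency zero."""
    n = x.size
    xc = x - x.mean()
    g0 = float(np.dot(xc, xc)) / n
    L = int(np.floor(4.0 * (n / 100.0) ** (2.0 / 9.0)))
    s = g0
    for k in range(1, min(L, n - 1) + 1):
        gk = float(np.dot(xc[:-k], xc[k:])) / n
        s += 2.0 * (1.0 - k / (L + 1.0)) * gk
    return max(s, 0.0)


def geweke_diagnostic(chain, frac_first: float = 0.1, frac_last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain segments.

    z = (mean_first - mean_last) / sqrt(S_first(0)/n1 + S_last(0)/n2), with
    the spectral densities at zero estimated by Newey-West tapering.  For a
    stationary chain z is approximately standard normal.
    """
    x = np.asarray(chain, dtype=float)
    if x.size < 100:
        raise ValueError(f"geweke needs a chain of >= 100 samples, got {x.size}")
    n1 = int(frac_first * x.size)
    n2 = int(frac_last * x.size)
    first, last = x[:n1], x[-n2:]
    v1, v2 = _long_run_variance(first), _long_run_variance(last)
    if v1 <= 0 or v2 <= 0:
        raise ValueError("zero-variance chain segment: Geweke diagnostic undefined")
    return float((first.mean() - last.mean()) / np.sqrt(v1 / n1 + v2 / n2))


def posterior_predictive(
    chains: PosteriorChains,
    trials: pd.DataFrame,
    n_sims: int = 500,
    seed: int = 0,
    dt: float = 1e-3,
    n_bins: int = 60,
    check_convergence: bool = True,
) -> dict:
    """Average RT/accuracy predictions over posterior draws.

    For each of ``n_sims`` retained draws, a synthetic dataset matching the
    observed trial counts is simulated from the participant-level parameters
    of that draw; per (modality, difficulty, direction) cell the function
    returns normalized correct/error RT histograms (joint normalization: the
    two areas sum to 1) averaged over draws, alongside the observed
    histograms and accuracies.
    """
    if len(trials) == 0:
        raise ValueError("posterior_predictive needs a non-empty trial table")
    if check_convergence:
        bad = []
        for name in chains.group_mean_names:
            try:
                zsc = geweke_diagnostic(chains.get(name))
            except ValueError:
                continue
            if abs(zsc) >= 1.96:
                bad.append((name, round(zsc, 2)))
        if bad:
            warnings.warn(f"group-mean chains with |Geweke z| >= 1.96: {bad}", stacklevel=2)

    if "rt_s" not in trials.columns:
        trials = trials.rename(columns={"rt": "rt_s"})
    spec = chains.spec
    rng = np.random.default_rng(seed)
    model_cols = ["participant", "session", "difficulty", "direction"]
    edges = np.linspace(0.0, 3.0, n_bins + 1)
    binw = edges[1] - edges[0]

    n = len(trials)
    pid = trials["participant"].to_numpy()
    ses = trials["session"].astype(str).to_numpy()
    cell_key = trials[model_cols].astype(str).agg("|".join, axis=1).to_numpy()

    # per-trial parameter columns for a given draw index
    a_col = np.array([f"a({s})|p{p}" for p, s in zip(pid, ses)])
    t_col = np.array([f"ter({s})|p{p}" for p, s in zip(pid, ses)])
    v_col = np.empty(n, dtype=object)
    sv_col = np.array([f"sv({s})" for s in ses])
    st_col = np.array([f"st({s})" for s in ses])
    for i, row in enumerate(trials.itertuples()):
        v_col[i] = f"v({row.session},{row.difficulty},{row.direction})|p{row.participant}"

    col_of = {nm: j for j, nm in enumerate(chains.names)}
    ia = np.array([col_of[c] for c in a_col])
    it_ = np.array([col_of[c] for c in t_col])
    iv = np.array([col_of[c] for c in v_col])
    isv = np.array([col_of[c] for c in sv_col])
    ist = np.array([col_of[c] for c in st_col])
    retained = chains.chains[chains.n_burn :]
    draw_idx = rng.integers(0, retained.shape[0], size=n_sims)

    keys = sorted(set(map(tuple, trials[["session", "difficulty", "direction"]].itertuples(index=False))))
    acc_sum = {k: 0.0 for k in keys}
    hist_c = {k: np.zeros(n_bins) for k in keys}
    hist_e = {k: np.zeros(n_bins) for k in keys}
    masks = {
        k: (
            (ses == k[0])
            & (trials["difficulty"].to_numpy() == k[1])
            & (trials["direction"].to_numpy() == k[2])
        )
        for k in keys
    }

    for d in draw_idx:
        row = retained[d]
        upper, rt_sim, _ = simulate_trials_mixed(
            row[ia], row[iv], row[it_], row[isv], row[ist], z=spec.start_point, dt=dt, seed=rng
        )
        in_window = rt_sim <= edges[-1]  # responses past the window are censored
        for k in keys:
            msk = masks[k] & in_window
            tot = max(int(msk.sum()), 1)
            acc_sum[k] += upper[msk].mean() if msk.any() else 0.0
            hc, _ = np.histogram(rt_sim[msk & upper], bins=edges)
            he, _ = np.histogram(rt_sim[msk & ~upper], bins=edges)
            hist_c[k] += hc / (tot * binw)
            hist_e[k] += he / (tot * binw)

    out = {"bin_edges": edges.tolist(), "n_sims": n_sims, "cells": {}}
    corr = trials["correct"].to_numpy(dtype=bool)
    rt_obs = trials["rt_s"].to_numpy(dtype=float)
    for k in keys:
        msk = masks[k]
        tot = msk.sum()
        oc, _ = np.histogram(rt_obs[msk & corr], bins=edges)
        oe, _ = np.histogram(rt_obs[msk & ~corr], bins=edges)
        out["cells"]["|".join(k)] = {
            "n_trials": int(tot),
            "predicted_accuracy": acc_sum[k] / n_sims,
            "observed_accuracy": float(corr[msk].mean()),
            "predicted_hist_correct": (hist_c[k] / n_sims).tolist(),
            "predicted_hist_error": (hist_e[k] / n_sims).tolist(),
            "observed_hist_correct": (oc / (tot * binw)).tolist(),
            "observed_hist_error": (oe / (tot * binw)).tolist(),
        }
    return out
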