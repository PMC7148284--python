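"""End-to-end orchestration: data in (or synthesized), report out.

Stage order mirrors the analysis flow of the study: behavioral summaries and
K-S consistency, joystick trajectory metrics, the hierarchical DDM fit,
equivalence tests for every between-modality contrast plus the
easy-vs-difficult drift contrasts, and posterior predictive checks.  All
randomness flows from one master seed expanded per stage, so a report is
regenerable byte-identically from its config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, kinematics
from .cohort import GroupParameters, read_trials, synth_cohort, write_trials
from .design import DIRECTIONS, MODALITIES
from .equivalence import equivalence_test
from .hierarchical import ModelSpec, build_model, posterior_predictive, sample_posterior
from .trajectories import (
    SAMPLE_RATE,
    frame_to_trajectories,
    synth_trajectories_for_trials,
    trajectories_to_frame,
)

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    """Either ``trial_csv`` (+ optional ``trajectory_csv``) or a synthetic
    block must be present.  ``paper_scale`` switches the synthetic cohort and
    MCMC to the full study dimensions (21 participants x 960 trials/session,
    15,000/7,000 samples); the defaults are desk-scale."""

    out_dir: str = "joyddm_out"
    seed: int = 0
    trial_csv: str | None = None
    trajectory_csv: str | None = None
    synthetic: dict | None = None  # n_participants, n_blocks, reps_per_cell, shared_modalities
    mcmc: dict = field(default_factory=lambda: {"n_total": 3000, "n_burn": 1000})
    inference: dict = field(default_factory=lambda: {"mass": 0.95})
    predictive: dict = field(default_factory=lambda: {"n_sims": 100})
    paper_scale: bool = False

    def __post_init__(self) -> None:
        if self.trial_csv is None and self.synthetic is None:
            raise ValueError("config needs either 'trial_csv' or a 'synthetic' block")
        if self.paper_scale:
            self.synthetic = {**(self.synthetic or {}), "n_participants": 21,
                              "n_blocks": 8, "reps_per_cell": 15}
            self.mcmc = {"n_total": 15_000, "n_burn": 7_000}
            self.predictive = {"n_sims": 500}
        if not self.mcmc["n_total"] > self.mcmc["n_burn"]:
            raise ValueError("mcmc n_total must exceed n_burn")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def hash(self) -> str:
        # out_dir is where the report lands, not part of its identity
        payload = json.dumps(
            {k: v for k, v in self.__dict__.items() if k != "out_dir"},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    behavior_summary: pd.DataFrame
    ks_consistency: dict
    trajectory_metrics: pd.DataFrame | None
    posterior_summary: pd.DataFrame
    equivalence: list
    predictive: dict
    provenance: dict


def _stage_seeds(master: int, n: int = 6) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def validate_inputs(trial_csv, trajectory_csv=None) -> dict:
    """Schema and range checks; returns {'errors': [...], 'warnings': [...]}."""
    errors, warnings_ = [], []
    try:
        trials = read_trials(trial_csv)
    except Exception as exc:  # unreadable / malformed header
        return {"errors": [f"trial table: {exc}"], "warnings": []}

    bad_rt = trials[(trials["rt_s"] <= 0) | (trials["rt_s"] > 3.0)]
    if len(bad_rt):
        errors.append(
            f"{len(bad_rt)} trial(s) with RT outside the (0, 3.0] s response window "
            f"(first: participant {bad_rt.iloc[0]['participant']}, trial {bad_rt.iloc[0]['trial']})"
        )
    bad_ses = set(trials["session"].unique()) - set(MODALITIES)
    if bad_ses:
        errors.append(f"unknown session labels: {sorted(bad_ses)}")
    bad_dir = set(trials["direction"].unique()) - set(DIRECTIONS)
    if bad_dir:
        errors.append(f"unknown direction labels: {sorted(bad_dir)}")

    if trajectory_csv is not None:
        try:
            tdf = pd.read_csv(trajectory_csv)
        except Exception as exc:
            return {"errors": errors + [f"trajectory table: {exc}"], "warnings": warnings_}
        need = {"participant", "trial", "t_s", "x", "y"}
        if not need <= set(tdf.columns):
            errors.append(f"trajectory table missing columns: {sorted(need - set(tdf.columns))}")
        else:
            for (pid, tid), g in tdf.groupby(["participant", "trial"]):
                t = g["t_s"].to_numpy()
                if np.any(np.diff(t) <= 0):
                    errors.append(f"non-increasing timestamps in participant {pid} trial {tid}")
                    break
            if np.abs(tdf[["x", "y"]].to_numpy()).max() > 1.0 + 1e-9:
                errors.append("trajectory deflections outside [-1, 1]")
            dt_med = tdf.groupby(["participant", "trial"])["t_s"].apply(
                lambda s: np.median(np.diff(s)) if len(s) > 1 else np.nan
            )
            if np.nanmax(np.abs(dt_med - 1.0 / SAMPLE_RATE)) > 1e-6:
                warnings_.append("trajectory sampling deviates from the 85 Hz grid")
            joy = trials[trials["session"] == "joystick"]
            have = set(map(tuple, tdf[["participant", "trial"]].drop_duplicates().itertuples(index=False)))
            want = set(map(tuple, joy[["participant", "trial"]].itertuples(index=False)))
            missing = want - have
            if missing:
                warnings_.append(f"{len(missing)} joystick trial(s) without a trajectory")
    return {"errors": errors, "warnings": warnings_}


def _modality_contrasts(chains, mass):
    out = []
    for base in ("a", "ter", "sv", "st"):
        out.append(
            equivalence_test(
                chains.get(f"{base}(joystick)"),
                chains.get(f"{base}(keyboard)"),
                label=f"{base}: joystick vs keyboard",
                mass=mass,
            )
        )
    for diff in chains.spec.difficulties:
        for d in chains.spec.directions:
            out.append(
                equivalence_test(
                    chains.get(f"v(joystick,{diff},{d})"),
                    chains.get(f"v(keyboard,{diff},{d})"),
                    label=f"v({diff},{d}): joystick vs keyboard",
                    mass=mass,
                )
            )
    for d in chains.spec.directions:
        easy = (chains.get(f"v(joystick,easy,{d})") + chains.get(f"v(keyboard,easy,{d})")) / 2.0
        hard = (
            chains.get(f"v(joystick,difficult,{d})") + chains.get(f"v(keyboard,difficult,{d})")
        ) / 2.0
        out.append(
            equivalence_test(easy, hard, label=f"v({d}): easy vs difficult", mass=mass)
        )
    return out


def run_pipeline(config: PipelineConfig, progress: bool = False) -> AnalysisReport:
    """Execute every stage and serialize the report under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    stage = "load"
    try:
        if config.trial_csv is not None:
            trials = read_trials(config.trial_csv)
            trajs = (
                frame_to_trajectories(pd.read_csv(config.trajectory_csv))
                if config.trajectory_csv
                else None
            )
        else:
            syn = dict(config.synthetic)
            shared = syn.pop("shared_modalities", False)
            group = GroupParameters()
            if shared:
                group = group.shared_across_modalities()
            _, trials, _ = synth_cohort(
                n_participants=syn.get("n_participants", 8),
                seed=seeds[0],
                n_blocks=syn.get("n_blocks", 2),
                reps_per_cell=syn.get("reps_per_cell", 15),
                group_params=group,
            )
            trajs = synth_trajectories_for_trials(trials, seed=seeds[1])
            write_trials(trials, out / "trials.csv")
            trajectories_to_frame(trajs).to_csv(out / "trajectories.csv", index=False)

        stage = "behavior"
        summary = behavior.summarize(trials)
        summary.to_csv(out / "behavior_summary.csv", index=False, float_format="%.6f")
        ks = behavior.ks_consistency(trials)
        ks_out = {
            "correlations": ks["correlations"],
            "per_participant": ks["per_participant"].round(6).to_dict(orient="records"),
        }
        _dump_json(ks_out, out / "ks_consistency.json")

        stage = "trajectory_metrics"
        traj_metrics = None
        if trajs is not None:
            traj_metrics = kinematics.metrics_table(trajs, trials)
            traj_metrics.to_csv(out / "trajectory_metrics.csv", index=False, float_format="%.6f")

        stage = "fit"
        model = build_model(trials, ModelSpec())
        chains = sample_posterior(
            model,
            n_total=config.mcmc["n_total"],
            n_burn=config.mcmc["n_burn"],
            seed=seeds[2],
            progress=progress,
        )
        post = chains.summary()
        post.to_csv(out / "posterior_summary.csv", index=False, float_format="%.6f")
        gcols = chains.group_mean_names
        chains.to_frame()[gcols].round(6).to_csv(out / "chains_group.csv", index=False)
        _dump_json(chains.provenance(), out / "chains_meta.json")

        stage = "equivalence"
        eq = _modality_contrasts(chains, config.inference.get("mass", 0.95))
        eq_rows = [
            {k: (round(v, 6) if isinstance(v, float) else v) for k, v in r.to_dict().items()}
            for r in eq
        ]
        _dump_json(eq_rows, out / "equivalence.json")

        stage = "predictive"
        pred = posterior_predictive(
            chains, trials, n_sims=config.predictive.get("n_sims", 100), seed=seeds[3]
        )
        _dump_json(_round_tree(pred), out / "predictive.json")

        stage = "report"
        provenance = {
            "config_hash": config.hash(),
            "master_seed": config.seed,
            "stage_seeds": seeds,
            "spec_hash": chains.spec.hash(),
            "n_trials": int(len(trials)),
            "n_participants": int(trials["participant"].nunique()),
        }
        report = {
            "provenance": provenance,
            "behavior_summary": summary.round(6).to_dict(orient="records"),
            "ks_correlations": ks["correlations"],
            "posterior_summary": post.round(6).to_dict(orient="records"),
            "equivalence": eq_rows,
        }
        _dump_json(report, out / "report.json")
    except Exception as exc:
        manifest = {"failed_stage": stage, "error": str(exc)}
        _dump_json(manifest, out / "partial_report_manifest.json")
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc

    return AnalysisReport(
        behavior_summary=summary,
        ks_consistency=ks,
        trajectory_metrics=traj_metrics,
        posterior_summary=post,
        equivalence=eq_rows,
        predictive=pred,
        provenance=provenance,
    )


def _round_tree(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_tree(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_tree(v, ndigits) for v in obj]
    return obj


def _dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
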