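import numpy as np
import pandas as pd
import pytest

from joyddm.ddm import DDMParameters, simulate_trials
from joyddm.hierarchical import (
    ModelSpec,
    PosteriorChains,
    build_model,
    geweke_diagnostic,
    posterior_predictive,
    sample_posterior,
)


class TestBuildModel:
    def test_sixteen_drift_group_means(self):
        spec = ModelSpec()
        assert spec.n_v_cells == 16
        assert spec.n_group_means == 24
        labels = {spec.v_label(c) for c in range(16)}
        assert "v(joystick,easy,up)" in labels and "v(keyboard,difficult,right)" in labels
        assert len(labels) == 16

    def test_free_start_point_rejected(self, tiny_cohort):
        _, trials, _ = tiny_cohort
        with pytest.raises(ValueError, match="fixed at 0.5"):
            build_model(trials, ModelSpec(estimate_start_point=True))

    def test_empty_cell_rejected_with_cell_name(self, tiny_cohort):
        _, trials, _ = tiny_cohort
        broken = trials[
            ~(
                (trials["participant"] == 1)
                & (trials["session"] == "joystick")
                & (trials["difficulty"] == "easy")
                & (trials["direction"] == "up")
            )
        ]
        with pytest.raises(ValueError, match=r"participant 1 .*v\(joystick,easy,up\)"):
            build_model(broken)

    def test_single_participant_hierarchy_collapses_gracefully(self):
        from joyddm.cohort import synth_cohort

        _, trials, _ = synth_cohort(n_participants=1, seed=3, n_blocks=1, reps_per_cell=3)
        model = build_model(trials)
        chains = sample_posterior(model, n_total=80, n_burn=40, seed=0)
        assert np.isfinite(chains.get("a(joystick)")).all()


class TestSamplePosterior:
    def test_retained_length_and_determinism(self, tiny_cohort):
        _, trials, _ = tiny_cohort
        model = build_model(trials)
        c1 = sample_posterior(model, n_total=120, n_burn=50, seed=11)
        c2 = sample_posterior(model, n_total=120, n_burn=50, seed=11)
        assert c1.n_retained == 70
        assert all(c1.get(n).size == 70 for n in c1.group_mean_names)
        assert np.array_equal(c1.chains, c2.chains)
        c3 = sample_posterior(model, n_total=120, n_burn=50, seed=12)
        assert not np.array_equal(c1.chains, c3.chains)

    def test_burnin_must_be_shorter_than_total(self, tiny_cohort):
        _, trials, _ = tiny_cohort
        model = build_model(trials)
        with pytest.raises(ValueError):
            sample_posterior(model, n_total=100, n_burn=100)

    def test_chain_samples_respect_parameter_domains(self, tiny_cohort):
        _, trials, _ = tiny_cohort
        model = build_model(trials)
        c = sample_posterior(model, n_total=150, n_burn=50, seed=2)
        for m in ("joystick", "keyboard"):
            assert (c.get(f"a({m})") > 0).all()
            assert (c.get(f"sv({m})") >= 0).all()
            assert (c.get(f"st({m})") >= 0).all()
            assert (c.get(f"ter({m})") - c.get(f"st({m})") / 2 >= 0).all()

    def test_provenance_recorded(self, tiny_cohort):
        _, trials, _ = tiny_cohort
        model = build_model(trials)
        c = sample_posterior(model, n_total=60, n_burn=20, seed=5)
        prov = c.provenance()
        assert prov["seed"] == 5 and prov["n_total"] == 60 and prov["n_burn"] == 20
        assert all(np.isfinite(v) for v in prov["acceptance_rates"].values())


class TestGeweke:
    def test_null_calibration_on_iid_chains(self):
        rng = np.random.default_rng(0)
        inside = sum(
            abs(geweke_diagnostic(rng.standard_normal(8000))) < 1.96 for _ in range(500)
        )
        assert inside / 500 >= 0.94

    def test_trending_chain_flagged(self):
        rng = np.random.default_rng(1)
        chain = 0.001 * np.arange(8000) + rng.standard_normal(8000)
        assert abs(geweke_diagnostic(chain)) > 1.96

    def test_constant_chain_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            geweke_diagnostic(np.full(1000, 2.0))

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            geweke_diagnostic(np.arange(50))


def _degenerate_chains(trials, params: DDMParameters, n_samples=300):
    """PosteriorChains in which every draw is the same parameter vector."""
    spec = ModelSpec()
    pids = sorted(trials["participant"].unique())
    names, values = [], []
    for m in spec.modalities:
        names += [f"a({m})", f"ter({m})", f"sv({m})", f"st({m})"]
        values += [params.a, params.ter, params.sv, params.st]
    names += [spec.v_label(c) for c in range(16)]
    values += [params.v] * 16
    for m in spec.modalities:
        names += [f"sigma_a({m})", f"sigma_ter({m})"]
        values += [0.0, 0.0]
    names += [f"sigma_{spec.v_label(c)}" for c in range(16)]
    values += [0.0] * 16
    for pid in pids:
        for m in spec.modalities:
            names += [f"a({m})|p{pid}", f"ter({m})|p{pid}"]
            values += [params.a, params.ter]
        names += [f"{spec.v_label(c)}|p{pid}" for c in range(16)]
        values += [params.v] * 16
    chains = np.tile(np.asarray(values), (n_samples, 1))
    return PosteriorChains(
        names=names, chains=chains, n_total=n_samples, n_burn=0, seed=0, spec=spec,
        participants=pids,
    )


@pytest.fixture(scope="module")
def degenerate_setup():
    params = DDMParameters(a=1.5, v=1.2, ter=0.45, sv=0.3, st=0.2)
    rows = []
    rng = np.random.default_rng(8)
    for ses in ("joystick", "keyboard"):
        upper, rt, _ = simulate_trials(params, 200, dt=1e-3, seed=rng)
        for i, (u, r) in enumerate(zip(upper, rt)):
            rows.append((1, ses, 1, i + 1, "easy", "up", u, min(r, 2.999)))
    trials = pd.DataFrame(
        rows,
        columns=["participant", "session", "block", "trial", "difficulty", "direction",
                 "correct", "rt_s"],
    )
    return params, trials


class TestPosteriorPredictive:
    def test_degenerate_posterior_matches_direct_simulation(self, degenerate_setup):
        params, trials = degenerate_setup
        chains = _degenerate_chains(trials, params)
        pred = posterior_predictive(chains, trials, n_sims=60, seed=1, check_convergence=False)
        upper, rt, _ = simulate_trials(params, 20_000, dt=1e-3, seed=99)
        direct_acc = upper[rt <= 3.0].mean()
        for cell in pred["cells"].values():
            assert cell["predicted_accuracy"] == pytest.approx(direct_acc, abs=0.03)

    def test_histograms_integrate_to_one(self, degenerate_setup):
        params, trials = degenerate_setup
        chains = _degenerate_chains(trials, params)
        pred = posterior_predictive(chains, trials, n_sims=20, seed=2, check_convergence=False)
        edges = np.asarray(pred["bin_edges"])
        binw = edges[1] - edges[0]
        for cell in pred["cells"].values():
            obs = (np.sum(cell["observed_hist_correct"]) + np.sum(cell["observed_hist_error"])) * binw
            sim = (np.sum(cell["predicted_hist_correct"]) + np.sum(cell["predicted_hist_error"])) * binw
            assert obs == pytest.approx(1.0, abs=1e-9)
            assert sim == pytest.approx(1.0, abs=1e-9)

    def test_empty_trials_rejected(self, degenerate_setup):
        params, trials = degenerate_setup
        chains = _degenerate_chains(trials, params)
        with pytest.raises(ValueError):
            posterior_predictive(chains, trials.iloc[:0], n_sims=5, seed=0)
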