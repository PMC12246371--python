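"""Hierarchical sampler, likelihood, diagnostics and DIC checks.

Likelihood sums are validated against a naive per-trial oracle; the
diagnostics against known processes (shifted normals, AR(1)); the sampler
against the prior (likelihood switched off) and against seeded
reproducibility.
"""

import copy
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import truncnorm

from sretddm.ddm import DDMParameters, wfpt_log_density
from sretddm.design import CELLS, GroupTruth, StudyDesign
from sretddm.hddm import (
    MCMCSettings,
    MODEL_VARIANTS,
    ModelSpec,
    Priors,
    autocorrelation,
    build_design,
    compute_dic,
    gelman_rubin,
    log_likelihood,
    sample_posterior,
)
from sretddm.synthetic import generate_dataset

TINY = MCMCSettings(n_samples=300, burn_in=100, thin=2, n_chains=2, seed=3)


@pytest.fixture(scope="module")
def tiny_trials():
    return generate_dataset(GroupTruth(), StudyDesign(n_participants=3), seed=15)


class TestModelSpec:
    def test_variant_names(self):
        assert [m.name for m in MODEL_VARIANTS] == [
            "null", "t", "v", "vt", "vz", "z", "zt",
        ]

    def test_boundary_variation_rejected(self):
        with pytest.raises(ValueError, match="converge"):
            ModelSpec(("a", "v"))

    def test_design_layout(self):
        d = build_design(ModelSpec(("v",)))
        assert len(d["v"]) == 4 and d["z"] == ["z"] and d["t"] == ["t"]
        d = build_design(ModelSpec(("v", "z")))
        assert len(d["v"]) == 4 and len(d["z"]) == 4 and d["t"] == ["t"]
        d = build_design(ModelSpec(()))
        assert [len(d[p]) for p in "vzta"] == [1, 1, 1, 1]


class TestSettings:
    def test_retained_draw_arithmetic(self):
        s = MCMCSettings()
        assert (s.n_samples, s.burn_in, s.thin) == (30_000, 5_000, 10)
        assert s.n_retained == 2_500

    def test_invalid_settings(self):
        with pytest.raises(ValueError):
            MCMCSettings(n_samples=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCSettings(thin=0)


class TestLogLikelihood:
    def test_single_trial_equals_density(self):
        df = pd.DataFrame(
            {
                "participant_id": [1],
                "condition": ["blue_enriched"],
                "valence": ["negative"],
                "response": [1],
                "rt": [0.8],
            }
        )
        got = log_likelihood(df, 1.36, 1.42, 0.49, 0.46)
        want = wfpt_log_density(0.8, "upper", DDMParameters(1.36, 1.42, 0.49, 0.46))
        assert got == pytest.approx(want, rel=1e-12)

    def test_duplication_doubles(self, tiny_trials):
        v = {c: GroupTruth().v_mean[c] for c in CELLS}
        one = log_likelihood(tiny_trials, v, 1.42, 0.49, 0.3)
        two = log_likelihood(
            pd.concat([tiny_trials, tiny_trials], ignore_index=True),
            v, 1.42, 0.49, 0.3,
        )
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_matches_naive_oracle(self, tiny_trials):
        """Kernel sum against a plain python loop over the density."""
        df = tiny_trials.head(20)
        v = {c: GroupTruth().v_mean[c] for c in CELLS}
        a_map = {1: 1.3, 2: 1.5, 3: 1.6}
        z_map = {1: 0.45, 2: 0.5, 3: 0.55}
        t_map = {1: 0.3, 2: 0.25, 3: 0.35}
        got = log_likelihood(df, v, a_map, z_map, t_map)
        want = 0.0
        for _, row in df.iterrows():
            params = DDMParameters(
                v[(row.condition, row.valence)],
                a_map[row.participant_id],
                z_map[row.participant_id],
                t_map[row.participant_id],
            )
            want += wfpt_log_density(
                row.rt, "upper" if row.response == 1 else "lower", params
            )
        assert got == pytest.approx(want, abs=1e-10)

    def test_impossible_trial_propagates(self, tiny_trials):
        # non-decision time above every rt: zero density
        assert log_likelihood(tiny_trials, 1.0, 1.4, 0.5, 10.0) == -np.inf


class TestSampler:
    def test_seeded_runs_identical(self, tiny_trials):
        a = sample_posterior(tiny_trials, ModelSpec(("v",)), settings=TINY)
        b = sample_posterior(tiny_trials, ModelSpec(("v",)), settings=TINY)
        for name in a.draws:
            np.testing.assert_array_equal(a.draws[name], b.draws[name])

    def test_retained_count(self, tiny_trials):
        fit = sample_posterior(tiny_trials, ModelSpec(("v",)), settings=TINY)
        assert all(arr.shape == (2, TINY.n_retained) for arr in fit.draws.values())

    def test_prior_only_recovers_prior_moments(self, tiny_trials):
        """With the likelihood off, draws reproduce the prior's moments."""
        pri = Priors()
        settings = MCMCSettings(
            n_samples=6_000, burn_in=1_000, thin=2, n_chains=2, seed=9
        )
        fit = sample_posterior(
            tiny_trials, ModelSpec(("v",)), priors=pri,
            settings=settings, prior_only=True,
        )
        v = fit.pooled("v[negative:blue_enriched]")
        assert abs(v.mean()) < 0.2 and abs(v.std() - pri.v_sd) < 0.3
        lo, hi = pri.a_bounds
        alpha = (lo - pri.a_mean) / pri.a_sd
        beta = (hi - pri.a_mean) / pri.a_sd
        expect_a = truncnorm.mean(alpha, beta, loc=pri.a_mean, scale=pri.a_sd)
        assert fit.pooled("a").mean() == pytest.approx(expect_a, abs=0.1)

    def test_group_recovery_smoke(self, tiny_trials):
        """Even a short run should land near the generating values."""
        fit = sample_posterior(
            tiny_trials, ModelSpec(("v",)),
            settings=MCMCSettings(
                n_samples=800, burn_in=300, thin=2, n_chains=2, seed=5
            ),
        )
        assert fit.group_means["a"] == pytest.approx(1.42, abs=0.4)
        assert fit.group_means["t"] == pytest.approx(0.46, abs=0.12)


class TestDiagnostics:
    def test_identical_chains_rhat_one(self, rng):
        x = rng.normal(size=500)
        rhat = gelman_rubin({"p": np.stack([x, x])})
        assert rhat["p"] == pytest.approx(1.0, abs=0.02)

    def test_shifted_chains_flagged(self, rng):
        chains = np.stack([rng.normal(0, 1, 400), rng.normal(5, 1, 400)])
        assert gelman_rubin({"p": chains})["p"] > 1.5

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            gelman_rubin({"p": rng.normal(size=(1, 100))})

    def test_white_noise_autocorrelation_small(self, rng):
        x = rng.normal(size=4_000)
        acf = autocorrelation(x, max_lag=10)
        assert acf[0] == 1.0
        assert np.all(np.abs(acf[1:]) < 3 / math.sqrt(x.size) + 0.02)

    def test_ar1_autocorrelation(self, rng):
        phi = 0.9
        n = 20_000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        acf = autocorrelation(x, max_lag=3)
        assert acf[1] == pytest.approx(phi, abs=0.03)

    def test_thinning_reduces_lag_one_autocorrelation(self, rng):
        phi = 0.9
        n = 30_000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        assert autocorrelation(x[::10], max_lag=1)[1] < autocorrelation(x, 1)[1]

    def test_constant_sequence_rejected(self):
        with pytest.raises(ValueError):
            autocorrelation(np.ones(100))

    def test_rhat_agrees_with_arviz(self, rng):
        """Cross-check against the independent rank-normalized estimator:
        both sit near 1 for well-mixed chains and far above 1.1 for
        disjoint ones."""
        import arviz as az

        good = rng.normal(size=(4, 500))
        ours = gelman_rubin({"p": good})["p"]
        theirs = float(az.rhat(az.convert_to_dataset(good[None].transpose(1, 0, 2)
                                                     .reshape(4, 500)))["x"])
        assert abs(ours - 1.0) < 0.02 and abs(theirs - 1.0) < 0.02
        bad = np.stack([rng.normal(0, 1, 500), rng.normal(4, 1, 500)])
        assert gelman_rubin({"p": bad})["p"] > 1.5
        assert float(az.rhat(az.convert_to_dataset(bad))["x"]) > 1.5


class TestDIC:
    def test_collapsed_posterior_has_zero_complexity(self, tiny_trials):
        """If every draw equals the posterior mean, pD = 0 and DIC is the
        deviance at that point."""
        fit = sample_posterior(tiny_trials, ModelSpec(("v",)), settings=TINY)
        collapsed = copy.deepcopy(fit)
        for name in collapsed.draws:
            collapsed.draws[name][:] = fit.draws[name].mean()
        pm = collapsed.participant_means
        gm = {n: float(collapsed.draws[n].mean()) for n in collapsed.draws}
        pm["a"] = gm["a"] + np.array(
            [gm[f"a_dev[{i}]"] for i in range(len(pm))]
        )
        pm["z"] = gm["z"] + np.array([gm[f"z_dev[{i}]"] for i in range(len(pm))])
        pm["t"] = gm["t"] + np.array([gm[f"t_dev[{i}]"] for i in range(len(pm))])
        v = {
            c: gm[n] for c, n in zip(CELLS, build_design(fit.spec)["v"])
        }
        ll = __import__("sretddm.hddm", fromlist=["log_likelihood"]).log_likelihood(
            tiny_trials, v,
            dict(zip(pm.participant_id, pm.a)),
            dict(zip(pm.participant_id, pm.z)),
            dict(zip(pm.participant_id, pm.t)),
        )
        collapsed.deviance[:] = -2.0 * ll
        dic, pd_eff = compute_dic(collapsed, tiny_trials)
        assert pd_eff == pytest.approx(0.0, abs=1e-8)
        assert dic == pytest.approx(-2.0 * ll, abs=1e-8)

    def test_null_model_has_fewer_effective_parameters(self, tiny_trials):
        fit_v = sample_posterior(tiny_trials, ModelSpec(("v",)), settings=TINY)
        fit_0 = sample_posterior(tiny_trials, ModelSpec(()), settings=TINY)
        assert fit_0.pd_ < fit_v.pd_
        assert fit_v.pd_ > 0

    def test_model_ranking_table(self, tiny_trials):
        from sretddm.hddm import select_best_model

        table = select_best_model(
            tiny_trials, [ModelSpec(()), ModelSpec(("v",))], settings=TINY
        )
        assert set(table["model"]) == {"null", "v"}
        assert table["dic"].is_monotonic_increasing
        null_delta = table.loc[table["model"] == "null", "delta_dic_vs_null"]
        assert float(null_delta.iloc[0]) == 0.0
        assert "converged" in table.columns


class TestPriorSensitivity:
    def test_group_drift_insensitive_to_prior_width(self):
        """Doubling every prior SD moves the group drift means by < 0.1
        when the likelihood carries thousands of trials."""
        trials = generate_dataset(
            GroupTruth(), StudyDesign(n_participants=8), seed=31
        )
        settings = MCMCSettings(
            n_samples=1_500, burn_in=500, thin=5, n_chains=2, seed=8
        )
        base = sample_posterior(trials, ModelSpec(("v",)), settings=settings)
        wide = sample_posterior(
            trials, ModelSpec(("v",)), priors=Priors().scaled(2.0),
            settings=settings,
        )
        for name in [k for k in base.draws if k.startswith("v[")]:
            assert abs(base.group_means[name] - wide.group_means[name]) < 0.1
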