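"""Overlap rule, posterior summaries, contrasts and predictive checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hsettings, strategies as st
from scipy.stats import norm

from sretddm.design import CELLS, GroupTruth, StudyDesign
from sretddm.hddm import FitResult, MCMCSettings, ModelSpec, sample_posterior
from sretddm.posterior import (
    posterior_overlap,
    ppc_quantiles,
    summarize_posterior,
    drift_contrasts,
)
from sretddm.synthetic import generate_dataset


class TestOverlap:
    def test_identical_draws_fully_overlap(self, rng):
        x = rng.normal(size=5_000)
        res = posterior_overlap(x, x)
        assert res.overlap_mass == pytest.approx(1.0, abs=0.02)
        assert not res.significant

    def test_separated_distributions_do_not_overlap(self, rng):
        res = posterior_overlap(
            rng.normal(0, 1, 5_000), rng.normal(10, 1, 5_000)
        )
        assert res.overlap_mass == pytest.approx(0.0, abs=1e-3)
        assert res.significant and res.direction == -1

    def test_matches_closed_form_for_normal_pair(self, rng):
        """Equal-variance normals separated by delta overlap by
        2*Phi(-|delta|/2)."""
        n = 100_000
        res = posterior_overlap(rng.normal(0, 1, n), rng.normal(2, 1, n))
        expect = 2 * norm.cdf(-1.0)
        assert res.overlap_mass == pytest.approx(expect, abs=0.01)

    @given(delta=st.floats(0.0, 6.0))
    @hsettings(max_examples=20, deadline=None)
    def test_symmetry(self, delta):
        rng = np.random.default_rng(99)
        a = rng.normal(0, 1, 3_000)
        b = rng.normal(delta, 1.3, 3_000)
        ab = posterior_overlap(a, b).overlap_mass
        ba = posterior_overlap(b, a).overlap_mass
        assert ab == pytest.approx(ba, abs=5e-3)

    def test_significance_is_pure_threshold(self, rng):
        a = rng.normal(0, 1, 20_000)
        b = rng.normal(3.92, 1, 20_000)  # overlap 2*Phi(-1.96) ~ 0.050
        res = posterior_overlap(a, b)
        assert res.significant == (res.overlap_mass < 0.05)

    def test_degenerate_draws_rejected(self):
        with pytest.raises(ValueError):
            posterior_overlap(np.ones(100), np.random.default_rng(1).normal(size=100))


class TestSummaries:
    def test_constant_draws(self):
        table = summarize_posterior({"c": np.full(50, 3.0)})
        row = table.iloc[0]
        assert (row["mean"], row["sd"]) == (3.0, 0.0)
        assert row["ci_2.5"] == row["ci_97.5"] == 3.0

    def test_normal_draws_credible_interval(self, rng):
        x = rng.normal(1.36, 0.04, 200_000)
        row = summarize_posterior({"v": x}).iloc[0]
        assert row["mean"] == pytest.approx(1.36, abs=0.002)
        assert row["ci_2.5"] == pytest.approx(1.36 - 1.96 * 0.04, abs=0.003)
        assert row["ci_97.5"] == pytest.approx(1.36 + 1.96 * 0.04, abs=0.003)

    def test_uniform_draws_interval_limits(self, rng):
        x = rng.uniform(0, 1, 200_000)
        row = summarize_posterior({"u": x}).iloc[0]
        assert row["ci_2.5"] == pytest.approx(0.025, abs=0.005)
        assert row["ci_97.5"] == pytest.approx(0.975, abs=0.005)


def _fake_v_fit(cell_means, sd=0.04, n=4_000, seed=0) -> FitResult:
    """Hand-built drift-varying fit with normal posteriors per cell."""
    rng = np.random.default_rng(seed)
    names = [
        "v[positive:blue_depleted]", "v[positive:blue_enriched]",
        "v[negative:blue_depleted]", "v[negative:blue_enriched]",
    ]
    draws = {
        name: rng.normal(m, sd, size=(1, n)) for name, m in zip(names, cell_means)
    }
    return FitResult(
        spec=ModelSpec(("v",)),
        settings=MCMCSettings(n_samples=100, burn_in=10, thin=1, n_chains=1),
        draws=draws,
        deviance=np.zeros((1, n)),
        dic=np.nan, pd_=np.nan,
        rhat={k: 1.0 for k in draws},
        participant_means=pd.DataFrame(),
        group_means={k: float(v.mean()) for k, v in draws.items()},
    )


class TestDriftContrasts:
    def test_reported_cell_separation_is_significant(self):
        """Posterior SDs of ~0.04 around means 1.36 vs 1.13 overlap < 5%."""
        fit = _fake_v_fit([-0.73, -0.71, 1.13, 1.36])
        table = drift_contrasts(fit).set_index("contrast")
        neg = table.loc["negative: enriched - depleted"]
        assert neg["significant"] and neg["direction"] == 1
        pos = table.loc["positive: enriched - depleted"]
        assert not pos["significant"]

    def test_equal_cells_not_significant(self):
        fit = _fake_v_fit([1.0, 1.0, 1.0, 1.0])
        table = drift_contrasts(fit)
        assert not table["significant"].any()

    def test_requires_drift_varying_fit(self, small_trials):
        fit = sample_posterior(
            small_trials, ModelSpec(()),
            settings=MCMCSettings(n_samples=120, burn_in=40, thin=2, n_chains=2),
        )
        with pytest.raises(ValueError):
            drift_contrasts(fit)


@pytest.fixture(scope="module")
def fitted_small():
    trials = generate_dataset(GroupTruth(), StudyDesign(n_participants=6), seed=20)
    fit = sample_posterior(
        trials, ModelSpec(("v",)),
        settings=MCMCSettings(n_samples=1_200, burn_in=400, thin=4, n_chains=2, seed=6),
    )
    return trials, fit


class TestPPC:
    def test_five_percentiles_per_cell(self, fitted_small):
        trials, fit = fitted_small
        table = ppc_quantiles(fit, trials, n_sim_per_cell=200, seed=1)
        probs = sorted(table["prob"].unique())
        assert probs == [0.10, 0.30, 0.50, 0.70, 0.90]
        counts = table.groupby(
            ["participant_id", "condition", "valence", "boundary"]
        ).size()
        assert (counts == 5).all()

    def test_quantiles_nondecreasing_within_rows(self, fitted_small):
        trials, fit = fitted_small
        table = ppc_quantiles(fit, trials, n_sim_per_cell=200, seed=2)
        ok = table.dropna(subset=["simulated"])
        for _, grp in ok.groupby(
            ["participant_id", "condition", "valence", "boundary"]
        ):
            sim = grp.sort_values("prob")["simulated"].to_numpy()
            assert np.all(np.diff(sim) >= 0)

    def test_self_consistency_gap_small(self, fitted_small):
        """Data simulated from the fitted parameters line up with their own
        posterior predictive quantiles."""
        trials, fit = fitted_small
        table = ppc_quantiles(fit, trials, n_sim_per_cell=800, seed=3)
        ok = table[~table["flagged"]].dropna()
        gap = (ok["observed"] - ok["simulated"]).abs().median()
        assert gap < 0.08

    def test_outlier_trimming(self, fitted_small):
        trials, fit = fitted_small
        pid = trials["participant_id"].iloc[0]
        cell = trials[
            (trials["participant_id"] == pid)
            & (trials["condition"] == "blue_enriched")
            & (trials["valence"] == "negative")
        ]
        doctored = trials.copy()
        doctored.loc[cell.index, "rt"] = 0.8
        doctored.loc[cell.index, "response"] = 1
        outlier_ix = cell.index[0]
        doctored.loc[outlier_ix, "rt"] = 10.0
        table = ppc_quantiles(fit, doctored, n_sim_per_cell=100, seed=4)
        row = table[
            (table["participant_id"] == pid)
            & (table["condition"] == "blue_enriched")
            & (table["valence"] == "negative")
            & (table["boundary"] == "upper")
        ]
        assert (row["n_observed"] == len(cell) - 1).all()
        assert (row["observed"] <= 0.8 + 1e-9).all()

    def test_sparse_cells_flagged(self, fitted_small):
        trials, fit = fitted_small
        # keep only 3 trials for one participant-cell
        pid = trials["participant_id"].iloc[0]
        mask = (
            (trials["participant_id"] == pid)
            & (trials["condition"] == "blue_enriched")
            & (trials["valence"] == "negative")
        )
        reduced = pd.concat(
            [trials[~mask], trials[mask].head(3)], ignore_index=True
        )
        table = ppc_quantiles(fit, reduced, n_sim_per_cell=100, seed=5)
        row = table[
            (table["participant_id"] == pid)
            & (table["condition"] == "blue_enriched")
            & (table["valence"] == "negative")
        ]
        assert row["flagged"].all()
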