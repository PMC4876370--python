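"""Sampler-correctness checks: reference prior, R-hat, posterior targets."""

import numpy as np
import pytest
from scipy import integrate, stats

from mlar1.bayes import (
    MCMCSettings,
    PriorSpec,
    fit_bayes_fixed,
    fit_bayes_random,
    log_reference_prior_phi,
    rhat,
)
from mlar1.datagen import Condition, PanelDataset, generate_panel, generate_series

FAST = MCMCSettings(chains=4, iterations=1500, burn_in=750, seed=5)


class TestReferencePrior:
    def test_closed_form_at_center(self):
        assert log_reference_prior_phi(0.0) == pytest.approx(np.log(1 / np.pi))

    def test_normalization(self):
        val, _ = integrate.quad(
            lambda p: np.exp(log_reference_prior_phi(p)), -1, 1
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_symmetry_and_boundary(self):
        assert log_reference_prior_phi(0.9) == pytest.approx(
            log_reference_prior_phi(-0.9)
        )
        assert log_reference_prior_phi(1.0) == -np.inf
        assert log_reference_prior_phi(np.array([-1.5, 0.5]))[0] == -np.inf


class TestRhat:
    def test_iid_chains_give_unity(self, rng):
        draws = rng.standard_normal((2, 10_000))
        assert 0.99 < rhat(draws) < 1.01

    def test_separated_chains_explode(self, rng):
        draws = rng.standard_normal((2, 1000))
        draws[1] += 10
        assert rhat(draws) > 1.5

    def test_chain_label_permutation_invariance(self, rng):
        draws = rng.standard_normal((4, 500))
        assert rhat(draws) == pytest.approx(rhat(draws[::-1]))

    def test_degenerate_chains_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            rhat(np.ones((2, 100)))

    def test_agrees_with_arviz_split_rhat(self, rng):
        import arviz as az

        draws = rng.standard_normal((4, 2000)) + 0.1 * np.cumsum(
            rng.standard_normal((4, 2000)), axis=1
        ) / np.sqrt(np.arange(1, 2001))
        assert rhat(draws) == pytest.approx(
            float(az.rhat(draws, method="split")), abs=0.01
        )


class TestBayesFixed:
    def test_likelihood_domination_large_T(self):
        y = generate_series(0.0, 0.6, 1.0, 10_000, 11)
        panel = PanelDataset(
            scores=y[None, :],
            phi_true=[0.6],
            mu_true=[0.0],
            condition=Condition(T=10_000, N=1, gamma01=0.6, sigma_u1=0.25),
        )
        fit, summs = fit_bayes_fixed(panel, settings=FAST)
        assert abs(summs[0].mean("phi") - 0.6) < 0.02

    def test_degenerate_series_raises(self):
        panel_scores = np.ones((2, 10))
        panel = PanelDataset(
            scores=panel_scores + np.array([[0.0], [1.0]]),
            phi_true=[0.0, 0.0],
            mu_true=[1.0, 2.0],
            condition=Condition(T=10, N=2, gamma01=0.0, sigma_u1=0.1),
        )
        with pytest.raises(ValueError, match="degenerate"):
            fit_bayes_fixed(panel, settings=FAST)

    def test_conjugate_reduction_matches_quadrature(self):
        """With phi frozen at 0 the model is iid-normal; posterior moments
        of the mean must match a two-dimensional quadrature oracle."""
        rng = np.random.default_rng(3)
        y = rng.normal(0.7, 1.0, size=12)
        panel = PanelDataset(
            scores=y[None, :],
            phi_true=[0.0],
            mu_true=[0.7],
            condition=Condition(T=12, N=1, gamma01=0.0, sigma_u1=0.1),
        )
        settings = MCMCSettings(chains=4, iterations=4000, burn_in=1000, seed=8)
        _, summs = fit_bayes_fixed(panel, settings=settings, fix_phi=0.0)

        # quadrature over (mu, sigma): N(y|mu, sigma) x N(mu|0,2) x Gamma(sigma|2,2)
        mus = np.linspace(-2, 3, 400)
        sigs = np.linspace(0.05, 5, 400)
        M, S = np.meshgrid(mus, sigs, indexing="ij")
        loglik = -len(y) * np.log(S) - ((y[None, None, :] - M[..., None]) ** 2).sum(
            -1
        ) / (2 * S**2)
        logpost = (
            loglik + stats.norm.logpdf(M, 0, 2) + stats.gamma.logpdf(S, 2, scale=0.5)
        )
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        mu_mean = (w * M).sum()
        mu_sd = np.sqrt((w * (M - mu_mean) ** 2).sum())
        ess = 4 * 3000 / 20  # conservative effective sample size
        assert summs[0].mean("mu") == pytest.approx(
            mu_mean, abs=3 * mu_sd / np.sqrt(ess)
        )
        assert summs[0].sd("mu") == pytest.approx(mu_sd, rel=0.1)

    def test_flat_likelihood_recovers_uniform_phi(self):
        """With the innovation SD frozen far above the data scale, the exact
        stationary likelihood contributes only its sqrt(1-phi^2) initial
        term, which cancels the reference prior: phi's posterior is uniform
        on (-1, 1)."""
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1, size=3)
        panel = PanelDataset(
            scores=y[None, :],
            phi_true=[0.0],
            mu_true=[0.0],
            condition=Condition(T=3, N=1, gamma01=0.0, sigma_u1=0.1),
        )
        settings = MCMCSettings(chains=4, iterations=6000, burn_in=1000, seed=9)
        _, summs = fit_bayes_fixed(panel, settings=settings, fix_sigma_e=50.0)
        draws = summs[0].draws[summs[0].names.index("phi")].ravel()
        # uniform(-1,1): mean 0, sd 1/sqrt(3), CDF(0.5) = 0.75
        ess = draws.size / 20
        assert abs(draws.mean()) < 3 / np.sqrt(3 * ess)
        assert draws.std() == pytest.approx(1 / np.sqrt(3), rel=0.1)
        assert np.mean(draws < 0.5) == pytest.approx(0.75, abs=0.05)
        assert np.mean(draws < -0.5) == pytest.approx(0.25, abs=0.05)

    def test_replication_interval_is_average_of_individual_bounds(self, small_panel):
        fit, summs = fit_bayes_fixed(small_panel, settings=FAST)
        los = [s.cri("phi")[0] for s in summs]
        his = [s.cri("phi")[1] for s in summs]
        assert fit.ci_gamma01[0] == pytest.approx(np.mean(los))
        assert fit.ci_gamma01[1] == pytest.approx(np.mean(his))


class TestBayesRandom:
    def test_single_panel_recovery(self, medium_panel):
        fit, _ = fit_bayes_random(medium_panel, settings=FAST)
        assert abs(fit.gamma01_hat - 0.3) < 0.15

    def test_sigma_u1_support_strictly_positive(self, small_panel):
        _, summ = fit_bayes_random(small_panel, settings=FAST)
        assert np.all(summ.draws[summ.names.index("sigma_u1")] > 0)

    def test_individual_predictions_are_stationary(self, small_panel):
        fit, _ = fit_bayes_random(small_panel, settings=FAST)
        assert np.all(np.abs(fit.phi_individual) < 1)
        assert fit.n_nonstationary == 0

    def test_chains_mix(self, small_panel):
        _, summ = fit_bayes_random(
            small_panel, settings=MCMCSettings(chains=4, iterations=3000,
                                               burn_in=1500, seed=13)
        )
        rh = summ.rhat_all()
        assert rh.mean() < 1.05
        assert rh.max() < 1.2


class TestDrawArchive:
    def test_long_format_and_summary_roundtrip(self, tmp_path, small_panel):
        import json

        import pandas as pd

        _, summ = fit_bayes_random(small_panel, settings=FAST)
        csv = tmp_path / "draws.csv"
        summ.write_csv(csv)
        df = pd.read_csv(csv)
        P, C, L = summ.draws.shape
        assert len(df) == P * C * L
        assert set(df.columns) == {"parameter", "chain", "iteration", "value"}
        jsonf = tmp_path / "summary.json"
        summ.write_summary_json(jsonf)
        payload = json.loads(jsonf.read_text())
        assert payload["gamma01"]["mean"] == pytest.approx(summ.mean("gamma01"))
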