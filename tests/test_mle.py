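"""Likelihood-oracle, REML-dominance and recovery checks for the ML fits."""

import subprocess
import sys

import numpy as np
import pytest
from scipy import stats

from mlar1.datagen import Condition, PanelDataset, generate_panel, generate_series
from mlar1.mle import _RemlWork, fit_ar1_single, fit_mle_fixed, fit_mle_random


def exact_ar1_neg2ll(y, mu, phi, sigma):
    """Independent re-statement of the exact stationary AR(1) deviance.

    Written directly from the density: y_1 ~ N(mu, sigma^2/(1-phi^2)),
    y_t | y_{t-1} ~ N(mu + phi (y_{t-1} - mu), sigma^2).  Broadcasts over
    parameter grids (mu, phi, sigma must have a common shape).
    """
    T = y.size
    resid0 = y[0] - mu
    innov = (
        y[None, 1:] - mu[..., None] - phi[..., None] * (y[None, :-1] - mu[..., None])
        if np.ndim(mu)
        else y[1:] - mu - phi * (y[:-1] - mu)
    )
    S = (1 - phi**2) * resid0**2 + (innov**2).sum(axis=-1)
    return (
        2 * T * np.log(sigma)
        - np.log1p(-(phi**2))
        + S / sigma**2
        + T * np.log(2 * np.pi)
    )


def grid_search_mle(y, rounds=3, k=60):
    """Brute-force maximizer of the exact likelihood on a refining lattice."""
    mu_lo, mu_hi = y.min() - 1, y.max() + 1
    phi_lo, phi_hi = -0.999, 0.999
    ls_lo, ls_hi = np.log(y.std()) - 2, np.log(y.std()) + 2
    best = None
    for _ in range(rounds):
        mus = np.linspace(mu_lo, mu_hi, k)
        phis = np.linspace(phi_lo, phi_hi, k)
        lss = np.linspace(ls_lo, ls_hi, k)
        M, P, L = np.meshgrid(mus, phis, lss, indexing="ij")
        dev = exact_ar1_neg2ll(y, M, P, np.exp(L))
        i, j, l = np.unravel_index(np.argmin(dev), dev.shape)
        best = (mus[i], phis[j], np.exp(lss[l]), dev[i, j, l])
        dm, dp, dl = mus[1] - mus[0], phis[1] - phis[0], lss[1] - lss[0]
        mu_lo, mu_hi = mus[i] - 2 * dm, mus[i] + 2 * dm
        phi_lo = max(phis[j] - 2 * dp, -0.9999)
        phi_hi = min(phis[j] + 2 * dp, 0.9999)
        ls_lo, ls_hi = lss[l] - 2 * dl, lss[l] + 2 * dl
    return best


class TestSingleSeriesMLE:
    def test_consistency_at_large_T(self):
        y = generate_series(0.0, 0.6, 1.0, 100_000, 17)
        fit = fit_ar1_single(y)
        assert fit.converged
        assert abs(fit.phi_hat - 0.6) < 0.01

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_grid_search_oracle(self, seed):
        y = generate_series(0.3, 0.4, 1.2, 10, seed)
        fit = fit_ar1_single(y)
        mu_g, phi_g, sig_g, _ = grid_search_mle(y)
        assert abs(fit.phi_hat - phi_g) < 1e-3
        assert abs(fit.mu_hat - mu_g) < 1e-3
        assert abs(fit.sigma_e_hat - sig_g) < 1e-3

    def test_time_reversal_invariance(self):
        """The stationary Gaussian AR(1) likelihood is time-reversible."""
        y = generate_series(1.0, -0.5, 1.0, 40, 23)
        f = fit_ar1_single(y)
        b = fit_ar1_single(y[::-1])
        assert abs(f.phi_hat - b.phi_hat) < 1e-6

    def test_estimate_is_stationary_and_interval_ordered(self, small_panel):
        for n in range(small_panel.N):
            fit = fit_ar1_single(small_panel.scores[n])
            assert abs(fit.phi_hat) < 1
            lo, hi = fit.interval_phi
            assert lo <= fit.phi_hat <= hi

    def test_degenerate_series_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_ar1_single(np.ones(10))


class TestFixedModelAggregation:
    def test_zero_dispersion_panel(self):
        y = generate_series(0.0, 0.4, 1.0, 12, 3)
        panel = PanelDataset(
            scores=np.tile(y, (5, 1)),
            phi_true=np.full(5, 0.4),
            mu_true=np.zeros(5),
            condition=Condition(T=12, N=5, gamma01=0.4, sigma_u1=0.1),
        )
        fit = fit_mle_fixed(panel)
        assert fit.sigma_u1_hat == pytest.approx(0.0, abs=1e-12)

    def test_t_multiplier_uses_df_N_minus_2(self, small_panel):
        fit = fit_mle_fixed(small_panel, alpha=0.05)
        half_width = fit.ci_gamma01[1] - fit.gamma01_hat
        assert half_width / fit.se_gamma01 == pytest.approx(2.3060, abs=1e-3)

    def test_aggregates_are_means_and_sd(self, small_panel):
        fit = fit_mle_fixed(small_panel)
        phis = [f.phi_hat for f in fit.per_individual if f.converged]
        assert fit.gamma01_hat == pytest.approx(np.mean(phis))
        assert fit.sigma_u1_hat == pytest.approx(np.std(phis, ddof=1))


class TestRandomModelREML:
    def test_optimum_dominates_profiled_grid(self):
        """No point of a 50x50 variance-ratio grid beats the optimizer."""
        panel = generate_panel(Condition(T=6, N=4, gamma01=0.2, sigma_u1=0.3), 5)
        fit = fit_mle_random(panel)
        work = _RemlWork(panel)
        grid = np.concatenate([[0.0], np.geomspace(1e-4, 50, 49)])
        vals = np.array(
            [[work.criterion((l0, l1)) for l1 in grid] for l0 in grid]
        )
        assert fit.reml_criterion <= vals.min() + 1e-6

    def test_degenerate_hierarchy_recovery(self):
        cond = Condition(
            T=2000, N=25, gamma01=0.3, sigma_u1=1e-12, sigma_u0=0.0, gamma00=0.0
        )
        panel = generate_panel(cond, 9)
        fit = fit_mle_random(panel)
        assert fit.sigma_u1_hat < 0.02
        assert abs(fit.gamma01_hat - 0.3) < 0.02

    def test_matches_lme4_reference(self, tmp_path):
        """Same model in lme4 (REML, uncorrelated effects) agrees to 1e-4."""
        import pandas as pd

        panels = [
            generate_panel(Condition(10, 10, -0.3, 0.40), 100 + s)
            for s in range(10)
        ] + [
            generate_panel(Condition(25, 10, 0.6, 0.25), 200 + s)
            for s in range(10)
        ]
        ours = []
        for i, p in enumerate(panels):
            y = p.scores
            df = pd.DataFrame(
                {
                    "y": y[:, 1:].ravel(),
                    "ylag": y[:, :-1].ravel(),
                    "ind": np.repeat(np.arange(p.N), p.T - 1),
                }
            )
            df.to_csv(tmp_path / f"p{i}.csv", index=False)
            ours.append(fit_mle_random(p).gamma01_hat)
        rscript = tmp_path / "fit.R"
        rscript.write_text(
            """
            suppressMessages(library(lme4))
            args <- commandArgs(trailingOnly=TRUE)
            for (f in args) {
              d <- read.csv(f)
              m <- suppressMessages(lmer(
                y ~ ylag + (1|ind) + (0+ylag|ind), data=d, REML=TRUE,
                control=lmerControl(check.conv.singular="ignore")))
              cat(sprintf("%.10f\\n", fixef(m)["ylag"]))
            }
            """
        )
        out = subprocess.run(
            ["Rscript", str(rscript)]
            + [str(tmp_path / f"p{i}.csv") for i in range(len(panels))],
            capture_output=True,
            text=True,
            check=True,
        )
        theirs = [float(v) for v in out.stdout.split()]
        assert len(theirs) == len(ours)
        np.testing.assert_allclose(ours, theirs, atol=1e-4)

    def test_parameter_recovery_large_panel(self):
        """|bias| of the population autocorrelation < 0.02 at N = T = 100."""
        cond = Condition(T=100, N=100, gamma01=0.3, sigma_u1=0.25)
        est = [
            fit_mle_random(generate_panel(cond, seed)).gamma01_hat
            for seed in range(200)
        ]
        assert abs(np.mean(est) - 0.3) < 0.02

    def test_sign_symmetry_of_bias(self):
        """Biases at +c and -c mirror each other within Monte-Carlo error:
        positive bias at negative population autocorrelation and vice versa."""
        R = 300
        biases = {}
        for g in (0.6, -0.6):
            cond = Condition(T=10, N=10, gamma01=g, sigma_u1=0.25)
            est = [
                fit_mle_random(generate_panel(cond, seed)).gamma01_hat
                for seed in range(R)
            ]
            biases[g] = np.mean(est) - g
            se = np.std(est, ddof=1) / np.sqrt(R)
        assert biases[-0.6] > 0 > biases[0.6]
        assert abs(biases[0.6] + biases[-0.6]) < 3 * np.sqrt(2) * se

    def test_nonstationary_count_matches_predictions(self, small_panel):
        fit = fit_mle_random(small_panel)
        assert fit.n_nonstationary == int(np.sum(np.abs(fit.phi_individual) > 1))
        assert fit.sigma_u1_hat >= 0 and fit.sigma_u0_hat >= 0
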