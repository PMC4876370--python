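"""Orchestration of the full simulation study.

The default design grid crosses series length T in {10, 25}, panel size N
in {10, 25}, between-person autocorrelation SD in {0.25, 0.40} and
population autocorrelation in {-0.6, -0.3, 0, 0.3, 0.6} — 40 conditions —
with four estimators (MLE-F, MLE-R, BAY-F, BAY-R) and a configurable
number of replications per cell (2000 in the full study).

Seeding: every (condition, replication) pair gets its own RNG stream
derived from the master seed and the condition's *parameter values* (not
its grid position), so any cell can be re-run in isolation, in any grid,
with identical results.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bayes import (
    MCMCSettings,
    PriorSpec,
    fit_bayes_fixed,
    fit_bayes_random,
)
from .datagen import Condition, PanelDataset, generate_panel
from .mle import fit_mle_fixed, fit_mle_random
from .outcomes import ConditionSummary, ReplicationRecord, summarize_condition

__all__ = [
    "ESTIMATORS",
    "StudyConfig",
    "PRIOR_SENSITIVITY_TESTS",
    "replication_seed",
    "fit_one",
    "run_condition",
    "run_study",
    "run_prior_sensitivity",
]

log = logging.getLogger("mlar1")

ESTIMATORS = ("MLE-F", "MLE-R", "BAY-F", "BAY-R")

#: replication presets used in the study documentation
PRESETS = {"full": 2000, "smoke": 50}


@dataclass
class StudyConfig:
    """Configuration of a (possibly reduced) study run."""

    T_grid: tuple[int, ...] = (10, 25)
    N_grid: tuple[int, ...] = (10, 25)
    sigma_u1_grid: tuple[float, ...] = (0.25, 0.40)
    gamma01_grid: tuple[float, ...] = (-0.6, -0.3, 0.0, 0.3, 0.6)
    replications: int = 2000
    estimators: tuple[str, ...] = ESTIMATORS
    gamma00: float = 0.0
    sigma_u0: float = 1.0
    sigma_e: float = 1.0
    alpha: float = 0.05
    master_seed: int = 1
    priors: PriorSpec = field(default_factory=PriorSpec)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    random_effect_correlation: str = "none"
    standardize_innovations: bool = False
    output_dir: str = "study_output"

    def __post_init__(self) -> None:
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        for est in self.estimators:
            if est not in ESTIMATORS:
                raise ValueError(f"unknown estimator {est!r}")

    def conditions(self) -> list[Condition]:
        return [
            Condition(
                T=T,
                N=N,
                gamma01=g,
                sigma_u1=s,
                gamma00=self.gamma00,
                sigma_u0=self.sigma_u0,
                sigma_e=self.sigma_e,
            )
            for T in self.T_grid
            for N in self.N_grid
            for s in self.sigma_u1_grid
            for g in self.gamma01_grid
        ]

    # -- config file round trip -------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "priors" in d and isinstance(d["priors"], dict):
            d["priors"] = PriorSpec(
                **{k: tuple(v) for k, v in d["priors"].items()}
            )
        if "mcmc" in d and isinstance(d["mcmc"], dict):
            m = dict(d["mcmc"])
            if "rhat_thresholds" in m:
                m["rhat_thresholds"] = tuple(m["rhat_thresholds"])
            d["mcmc"] = MCMCSettings(**m)
        for k in ("T_grid", "N_grid", "sigma_u1_grid", "gamma01_grid", "estimators"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def replication_seed(master_seed: int, condition: Condition, r: int):
    """Independent RNG stream for one replication of one condition.

    The spawn key encodes the condition's parameter values, so the stream
    does not depend on where the condition sits in a grid.
    """
    key = (
        condition.T,
        condition.N,
        int(round((condition.gamma01 + 1.0) * 1000)),
        int(round(condition.sigma_u1 * 1000)),
        r,
    )
    return np.random.SeedSequence(master_seed, spawn_key=key)


def _chain_seed(seed_seq) -> int:
    # a deterministic 31-bit integer for the MCMC engine
    return int(seed_seq.generate_state(1, dtype=np.uint64)[0] % (2**31 - 1))


def fit_one(
    panel: PanelDataset,
    estimator: str,
    r: int,
    alpha: float = 0.05,
    priors: PriorSpec | None = None,
    mcmc: MCMCSettings | None = None,
    correlation: str = "none",
) -> ReplicationRecord:
    """Fit one estimator on one panel and condense it to a record."""
    N = panel.N
    if estimator == "MLE-F":
        fit = fit_mle_fixed(panel, alpha=alpha)
        lo, hi = fit.ci_gamma01
        return ReplicationRecord(
            estimator=estimator,
            replication=r,
            gamma01_hat=fit.gamma01_hat,
            se_gamma01=fit.se_gamma01,
            sigma_u1_hat=fit.sigma_u1_hat,
            interval=(lo, hi),
            rejected_h0=bool(lo > 0 or hi < 0),
            n_nonconverged=fit.n_nonconverged,
            n_individuals=N,
        )
    if estimator == "MLE-R":
        fit = fit_mle_random(panel, alpha=alpha, correlation=correlation)
        lo, hi = fit.ci_gamma01
        return ReplicationRecord(
            estimator=estimator,
            replication=r,
            gamma01_hat=fit.gamma01_hat,
            se_gamma01=fit.se_gamma01,
            sigma_u1_hat=fit.sigma_u1_hat,
            interval=(lo, hi),
            rejected_h0=bool(lo > 0 or hi < 0),
            n_nonstationary=fit.n_nonstationary,
            n_individuals=N,
            converged=fit.converged,
        )
    if estimator == "BAY-F":
        fit, _ = fit_bayes_fixed(panel, priors=priors, settings=mcmc, alpha=alpha)
        lo, hi = fit.ci_gamma01
        return ReplicationRecord(
            estimator=estimator,
            replication=r,
            gamma01_hat=fit.gamma01_hat,
            se_gamma01=fit.se_gamma01,
            sigma_u1_hat=fit.sigma_u1_hat,
            interval=(lo, hi),
            rejected_h0=bool(lo > 0 or hi < 0),
            n_individuals=N,
        )
    if estimator == "BAY-R":
        fit, _ = fit_bayes_random(panel, priors=priors, settings=mcmc, alpha=alpha)
        lo, hi = fit.ci_gamma01
        return ReplicationRecord(
            estimator=estimator,
            replication=r,
            gamma01_hat=fit.gamma01_hat,
            se_gamma01=fit.se_gamma01,
            sigma_u1_hat=fit.sigma_u1_hat,
            interval=(lo, hi),
            rejected_h0=bool(lo > 0 or hi < 0),
            n_individuals=N,
        )
    raise ValueError(f"unknown estimator {estimator!r}")


def run_condition(
    condition: Condition,
    estimator: str,
    R: int,
    master_seed: int,
    alpha: float = 0.05,
    priors: PriorSpec | None = None,
    mcmc: MCMCSettings | None = None,
    correlation: str = "none",
    standardize_innovations: bool = False,
) -> tuple[ConditionSummary, list[ReplicationRecord]]:
    """Run R seeded replications of one estimator in one design cell."""
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}")
    records: list[ReplicationRecord] = []
    mcmc = mcmc or MCMCSettings()
    t0 = time.monotonic()
    for r in range(R):
        ss = replication_seed(master_seed, condition, r)
        panel = generate_panel(
            condition, ss, standardize_innovations=standardize_innovations
        )
        mc = None
        if estimator.startswith("BAY"):
            mc = MCMCSettings(
                chains=mcmc.chains,
                iterations=mcmc.iterations,
                burn_in=mcmc.burn_in,
                seed=_chain_seed(ss),
                rhat_thresholds=mcmc.rhat_thresholds,
            )
        try:
            records.append(
                fit_one(
                    panel,
                    estimator,
                    r,
                    alpha=alpha,
                    priors=priors,
                    mcmc=mc,
                    correlation=correlation,
                )
            )
        except Exception as exc:  # failures are tallied, never fatal
            log.warning("replication %d failed: %s", r, exc)
            records.append(
                ReplicationRecord(
                    estimator=estimator,
                    replication=r,
                    gamma01_hat=float("nan"),
                    se_gamma01=float("nan"),
                    sigma_u1_hat=float("nan"),
                    interval=(float("nan"), float("nan")),
                    rejected_h0=False,
                    n_individuals=panel.N,
                    converged=False,
                )
            )
    summary = summarize_condition(records, condition)
    log.info(
        "%s %s R=%d done in %.1fs (epr=%.3f, bias=%.4f)",
        estimator,
        condition.label(),
        R,
        time.monotonic() - t0,
        summary.epr,
        summary.bias_gamma01,
    )
    return summary, records


def records_frame(records: list[ReplicationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = asdict(r)
        lo, hi = d.pop("interval")
        d["interval_lower"], d["interval_upper"] = lo, hi
        rows.append(d)
    return pd.DataFrame(rows)


def run_study(config: StudyConfig) -> pd.DataFrame:
    """Run the full conditions x estimators grid, resumably.

    Per-cell replication records are written incrementally to the output
    directory; cells whose record file already exists are skipped, and the
    summary table is (re)assembled from disk at the end, so an interrupted
    run can simply be restarted.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not outdir.is_dir():
        raise ValueError(f"unwritable output directory {outdir}")
    for cond in config.conditions():
        for est in config.estimators:
            cell = outdir / f"records_{est}_{cond.label()}.csv"
            if cell.exists():
                log.info("skipping completed cell %s", cell.name)
                continue
            _, records = run_condition(
                cond,
                est,
                config.replications,
                config.master_seed,
                alpha=config.alpha,
                priors=config.priors,
                mcmc=config.mcmc,
                correlation=config.random_effect_correlation,
                standardize_innovations=config.standardize_innovations,
            )
            records_frame(records).to_csv(cell, index=False, float_format="%.17g")
    # reassemble the full table from disk so resumed runs are complete
    table = _summaries_from_disk(config)
    table.to_csv(outdir / "summary.csv", index=False)
    return table


def _summaries_from_disk(config: StudyConfig) -> pd.DataFrame:
    outdir = Path(config.output_dir)
    rows = []
    for cond in config.conditions():
        for est in config.estimators:
            cell = outdir / f"records_{est}_{cond.label()}.csv"
            if not cell.exists():
                continue
            df = pd.read_csv(cell)
            records = [
                ReplicationRecord(
                    estimator=row.estimator,
                    replication=int(row.replication),
                    gamma01_hat=row.gamma01_hat,
                    se_gamma01=row.se_gamma01,
                    sigma_u1_hat=row.sigma_u1_hat,
                    interval=(row.interval_lower, row.interval_upper),
                    rejected_h0=bool(row.rejected_h0),
                    n_nonconverged=int(row.n_nonconverged),
                    n_nonstationary=int(row.n_nonstationary),
                    n_individuals=int(row.n_individuals),
                    converged=bool(row.converged),
                )
                for row in df.itertuples()
            ]
            rows.append(summarize_condition(records, cond).to_row())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# prior sensitivity (the nine-prior grid)

#: the nine prior settings of the sensitivity study: per test, hyperpriors
#: for the fixed model (mu_n, sigma_e_n) and the random model (gamma00,
#: sigma_u0, sigma_e, sigma_u1); tests 8-9 vary random-model hyperpriors
#: only and define no fixed-model variant
PRIOR_SENSITIVITY_TESTS: dict[int, dict] = {
    1: {"fixed": ((0, 2), (2, 2)), "random": ((0, 2), (2, 2), (2, 2), (2, 2))},
    2: {"fixed": ((0, 5), (2, 2)), "random": ((0, 5), (2, 2), (2, 2), (2, 2))},
    3: {"fixed": ((1, 2), (2, 2)), "random": ((1, 2), (2, 2), (2, 2), (2, 2))},
    4: {"fixed": ((1, 5), (2, 2)), "random": ((0, 2), (1, 1), (2, 2), (2, 2))},
    5: {"fixed": ((0, 2), (1, 1)), "random": ((0, 2), (1, 2), (2, 2), (2, 2))},
    6: {"fixed": ((0, 2), (1, 2)), "random": ((0, 2), (2, 2), (1, 1), (2, 2))},
    7: {"fixed": ((0, 2), (2, 1)), "random": ((0, 2), (2, 2), (1, 2), (2, 2))},
    8: {"fixed": None, "random": ((0, 2), (2, 2), (2, 2), (1, 1))},
    9: {"fixed": None, "random": ((0, 2), (2, 2), (2, 2), (1, 2))},
}


def prior_spec_for_test(test: int, model: str) -> PriorSpec | None:
    entry = PRIOR_SENSITIVITY_TESTS[test]
    if model == "fixed":
        if entry["fixed"] is None:
            return None
        mu, se = entry["fixed"]
        return PriorSpec(mu_prior=mu, sigma_e_prior=se)
    g00, su0, se, su1 = entry["random"]
    return PriorSpec(
        gamma00_prior=g00,
        sigma_u0_prior=su0,
        sigma_e_prior=se,
        sigma_u1_prior=su1,
    )


def run_prior_sensitivity(
    config: StudyConfig,
    tests: tuple[int, ...] = tuple(range(1, 10)),
) -> pd.DataFrame:
    """Re-run the prior-sensitivity experiment on its single design cell.

    The cell is T = N = 10, population autocorrelation 0 with
    between-person SD 0.40; each prior test runs both Bayesian estimators
    (the fixed model only where a fixed-model variant is defined) and
    reports the mean population-autocorrelation and mean intercept
    estimates over the replications.
    """
    cond = Condition(
        T=10,
        N=10,
        gamma01=0.0,
        sigma_u1=0.40,
        gamma00=config.gamma00,
        sigma_u0=config.sigma_u0,
        sigma_e=config.sigma_e,
    )
    rows = []
    for test in tests:
        for model, est in (("random", "BAY-R"), ("fixed", "BAY-F")):
            priors = prior_spec_for_test(test, model)
            if priors is None:
                continue
            g01s, mus = [], []
            for r in range(config.replications):
                ss = replication_seed(config.master_seed, cond, r)
                panel = generate_panel(cond, ss)
                mc = MCMCSettings(
                    chains=config.mcmc.chains,
                    iterations=config.mcmc.iterations,
                    burn_in=config.mcmc.burn_in,
                    seed=_chain_seed(ss),
                    rhat_thresholds=config.mcmc.rhat_thresholds,
                )
                if est == "BAY-R":
                    fit, summ = fit_bayes_random(
                        panel, priors=priors, settings=mc, alpha=config.alpha
                    )
                    g01s.append(fit.gamma01_hat)
                    mus.append(summ.mean("gamma00"))
                else:
                    fit, summs = fit_bayes_fixed(
                        panel, priors=priors, settings=mc, alpha=config.alpha
                    )
                    g01s.append(fit.gamma01_hat)
                    mus.append(float(np.mean([s.mean("mu") for s in summs])))
            rows.append(
                {
                    "test": test,
                    "estimator": est,
                    "mean_gamma01_hat": float(np.mean(g01s)),
                    "mean_mu_hat": float(np.mean(mus)),
                    "replications": config.replications,
                }
            )
            log.info("prior test %d %s done", test, est)
    return pd.DataFrame(rows)
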