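"""Replication-level outcome measures for the simulation study.

Given the per-replication estimates of one estimator in one design cell,
these functions compute the study's six outcome measures: bias of the
population autocorrelation, bias of its between-person SD, the empirical
(across-replication) SD of the estimate, the bias of the standard error,
the empirical rejection rate (type-I error when the true population
autocorrelation is zero, power otherwise), and the 2.5th/97.5th percentile
interval of the estimates — plus tallies of the computational problems
(non-convergence, non-stationary individual predictions).

All sample SDs use the n-1 denominator; percentile intervals use the
linear-interpolation quantile definition.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .datagen import Condition

__all__ = [
    "ReplicationRecord",
    "ConditionSummary",
    "bias_gamma01",
    "bias_sigma_u1",
    "empirical_sd",
    "bias_se",
    "epr",
    "interval_estimate",
    "summarize_condition",
]


@dataclass(frozen=True)
class ReplicationRecord:
    """One estimator's result on one replication.

    For the fixed estimators ``sigma_u1_hat`` is the within-replication SD
    of the individual autocorrelation estimates and ``se_gamma01`` the mean
    of their standard errors; for the random estimators both come directly
    from the population-level fit.
    """

    estimator: str
    replication: int
    gamma01_hat: float
    se_gamma01: float
    sigma_u1_hat: float
    interval: tuple[float, float]
    rejected_h0: bool
    n_nonconverged: int = 0
    n_nonstationary: int = 0
    n_individuals: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if np.isfinite(lo) and np.isfinite(hi) and lo > hi:
            raise ValueError("interval lower bound exceeds upper bound")


@dataclass(frozen=True)
class ConditionSummary:
    """All outcome measures for one (condition, estimator) cell."""

    estimator: str
    condition: Condition
    bias_gamma01: float
    bias_sigma_u1: float
    empirical_sd: float
    bias_se: float
    epr: float
    interval_lower: float
    interval_upper: float
    mean_gamma01: float
    pct_nonconverged: float
    pct_nonstationary: float
    R_effective: int

    def to_row(self) -> dict:
        row = asdict(self)
        cond = row.pop("condition")
        return {**cond, **row}


def _usable(records: Sequence[ReplicationRecord]) -> list[ReplicationRecord]:
    out = [r for r in records if r.converged]
    if not out:
        raise ValueError("no usable replication records")
    return out


def bias_gamma01(records: Sequence[ReplicationRecord], gamma01_true: float) -> float:
    """Mean of the population-autocorrelation estimates minus the truth."""
    recs = _usable(records)
    return float(np.mean([r.gamma01_hat for r in recs]) - gamma01_true)


def bias_sigma_u1(records: Sequence[ReplicationRecord], sigma_u1_true: float) -> float:
    """Mean of the between-person-SD estimates minus the truth."""
    recs = _usable(records)
    return float(np.mean([r.sigma_u1_hat for r in recs]) - sigma_u1_true)


def empirical_sd(records: Sequence[ReplicationRecord]) -> float:
    """Across-replication SD of the population-autocorrelation estimate."""
    recs = _usable(records)
    return float(np.std([r.gamma01_hat for r in recs], ddof=1))


def bias_se(records: Sequence[ReplicationRecord]) -> float:
    """Mean reported SE minus the empirical SD of the estimates."""
    recs = _usable(records)
    return float(np.mean([r.se_gamma01 for r in recs]) - empirical_sd(recs))


def epr(records: Sequence[ReplicationRecord]) -> float:
    """Fraction of replications whose interval excludes zero."""
    recs = _usable(records)
    return float(np.mean([r.rejected_h0 for r in recs]))


def interval_estimate(records: Sequence[ReplicationRecord]) -> tuple[float, float]:
    """2.5th and 97.5th percentiles of the estimates across replications."""
    recs = _usable(records)
    vals = np.array([r.gamma01_hat for r in recs])
    lo, hi = np.percentile(vals, [2.5, 97.5])  # linear interpolation
    return float(lo), float(hi)


def summarize_condition(
    records: Sequence[ReplicationRecord], condition: Condition
) -> ConditionSummary:
    """Assemble every outcome measure for one design cell.

    Replications with a failed fit are dropped from the measures and only
    enter the problem tallies; non-convergence and non-stationarity are
    counted per individual fit/prediction, not per panel.
    """
    recs = _usable(records)
    lo, hi = interval_estimate(recs)
    attempted = sum(r.n_individuals for r in records)
    n_nc = sum(r.n_nonconverged for r in records)
    n_ns = sum(r.n_nonstationary for r in records)
    return ConditionSummary(
        estimator=records[0].estimator,
        condition=condition,
        bias_gamma01=bias_gamma01(recs, condition.gamma01),
        bias_sigma_u1=bias_sigma_u1(recs, condition.sigma_u1),
        empirical_sd=empirical_sd(recs),
        bias_se=bias_se(recs),
        epr=epr(recs),
        interval_lower=lo,
        interval_upper=hi,
        mean_gamma01=float(np.mean([r.gamma01_hat for r in recs])),
        pct_nonconverged=100.0 * n_nc / attempted if attempted else 0.0,
        pct_nonstationary=100.0 * n_ns / attempted if attempted else 0.0,
        R_effective=len(recs),
    )
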