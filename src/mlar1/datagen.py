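"""Seeded generation of multilevel AR(1) panels.

Each individual ``n`` follows a stationary first-order autoregression

    y_t,n = mu_n + phi_n * (y_{t-1,n} - mu_n) + e_t,n,   e_t,n ~ N(0, sigma_e),

with person-specific means ``mu_n = gamma00 + U0_n`` (``U0_n`` normal) and
person-specific autocorrelations ``phi_n`` drawn from a normal distribution
truncated and renormalized to the stationary interval (-1, 1), centered at
the population autocorrelation ``gamma01`` with between-person spread
``sigma_u1``.  The first observation of every series is a draw from the
stationary marginal ``N(mu_n, sigma_e^2 / (1 - phi_n^2))``, so the series is
exactly stationary from t = 1 (no burn-in).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Condition",
    "PanelDataset",
    "sample_phi",
    "generate_series",
    "generate_panel",
    "write_panel",
    "read_panel",
]


@dataclass(frozen=True)
class Condition:
    """One cell of the simulation design grid.

    Parameters
    ----------
    T : int
        Number of time points per individual (>= 2).
    N : int
        Number of individuals per panel (>= 1).
    gamma01 : float
        Population mean of the autocorrelation distribution, in (-1, 1).
    sigma_u1 : float
        Between-person SD of the autocorrelation (before truncation), > 0.
    gamma00 : float
        Population intercept; the study design fixes it at 0.
    sigma_u0 : float
        Between-person SD of the intercept, >= 0.
    sigma_e : float
        Innovation SD, > 0 (the design fixes it at 1).
    """

    T: int
    N: int
    gamma01: float
    sigma_u1: float
    gamma00: float = 0.0
    sigma_u0: float = 1.0
    sigma_e: float = 1.0

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ValueError("T must be at least 2")
        if self.N < 1:
            raise ValueError("N must be at least 1")
        if not abs(self.gamma01) < 1:
            raise ValueError("gamma01 must lie strictly inside (-1, 1)")
        if not self.sigma_u1 > 0:
            raise ValueError("sigma_u1 must be positive")
        if self.sigma_u0 < 0:
            raise ValueError("sigma_u0 must be non-negative")
        if not self.sigma_e > 0:
            raise ValueError("sigma_e must be positive")

    def label(self) -> str:
        return (
            f"T{self.T}_N{self.N}_g{self.gamma01:+.2f}_s{self.sigma_u1:.2f}"
        )


@dataclass
class PanelDataset:
    """A generated panel together with the individual-level truth.

    ``scores`` has shape (N, T); ``phi_true`` and ``mu_true`` have length N.
    """

    scores: np.ndarray
    phi_true: np.ndarray
    mu_true: np.ndarray
    condition: Condition
    seed: int | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.phi_true = np.asarray(self.phi_true, dtype=float)
        self.mu_true = np.asarray(self.mu_true, dtype=float)
        N, T = self.scores.shape
        if T != self.condition.T or N != self.condition.N:
            raise ValueError("scores shape does not match condition (N, T)")
        if not np.all(np.abs(self.phi_true) < 1):
            raise ValueError("phi_true must lie strictly inside (-1, 1)")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite (no missing values)")

    @property
    def N(self) -> int:
        return self.scores.shape[0]

    @property
    def T(self) -> int:
        return self.scores.shape[1]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_phi(gamma01: float, sigma_u1: float, N: int, rng_seed) -> np.ndarray:
    """Draw N individual autocorrelations from the truncated normal on (-1, 1).

    The density is the N(gamma01, sigma_u1) density restricted to (-1, 1)
    and renormalized over that interval.
    """
    if not abs(gamma01) < 1:
        raise ValueError("gamma01 must lie strictly inside (-1, 1)")
    if not sigma_u1 > 0:
        raise ValueError("sigma_u1 must be positive")
    if N < 1:
        raise ValueError("N must be at least 1")
    rng = _as_rng(rng_seed)
    a = (-1.0 - gamma01) / sigma_u1
    b = (1.0 - gamma01) / sigma_u1
    draws = stats.truncnorm.rvs(
        a, b, loc=gamma01, scale=sigma_u1, size=N, random_state=rng
    )
    # guard against boundary round-off; draws are continuous so this is a no-op
    eps = 1e-12
    return np.clip(draws, -1.0 + eps, 1.0 - eps)


def generate_series(
    mu: float,
    phi: float,
    sigma_e: float,
    T: int,
    rng_seed,
    standardize_innovations: bool = False,
) -> np.ndarray:
    """Generate one stationary AR(1) series of length T.

    y_1 is drawn from the stationary distribution N(mu, sigma_e^2/(1-phi^2));
    subsequent values follow the AR(1) recursion.  With
    ``standardize_innovations`` the realized innovations are recentered and
    rescaled to sample mean 0 and sample SD 1 (n-1 denominator) before the
    recursion is applied, a literal reading of "error set to mean 0, SD 1".
    """
    if not abs(phi) < 1:
        raise ValueError("phi must lie strictly inside (-1, 1) (stationarity)")
    if not sigma_e > 0:
        raise ValueError("sigma_e must be positive")
    if T < 2:
        raise ValueError("T must be at least 2")
    rng = _as_rng(rng_seed)
    y0 = mu + sigma_e / np.sqrt(1.0 - phi * phi) * rng.standard_normal()
    e = sigma_e * rng.standard_normal(T - 1)
    if standardize_innovations:
        e = (e - e.mean()) / e.std(ddof=1)
    y = np.empty(T)
    y[0] = y0
    prev = y0 - mu
    for t in range(1, T):
        prev = phi * prev + e[t - 1]
        y[t] = mu + prev
    return y


def generate_panel(
    condition: Condition,
    rng_seed,
    standardize_innovations: bool = False,
) -> PanelDataset:
    """Generate a full panel of N series under one design condition.

    The individual truth (phi_n, mu_n) is retained alongside the scores.
    A fixed integer seed reproduces the panel bit-for-bit.
    """
    seed_repr = rng_seed if isinstance(rng_seed, (int, np.integer)) else None
    rng = _as_rng(rng_seed)
    phi = sample_phi(condition.gamma01, condition.sigma_u1, condition.N, rng)
    u0 = (
        condition.sigma_u0 * rng.standard_normal(condition.N)
        if condition.sigma_u0 > 0
        else np.zeros(condition.N)
    )
    mu = condition.gamma00 + u0
    scores = np.empty((condition.N, condition.T))
    for n in range(condition.N):
        scores[n] = generate_series(
            mu[n],
            phi[n],
            condition.sigma_e,
            condition.T,
            rng,
            standardize_innovations=standardize_innovations,
        )
    return PanelDataset(
        scores=scores,
        phi_true=phi,
        mu_true=mu,
        condition=condition,
        seed=None if seed_repr is None else int(seed_repr),
    )


# ---------------------------------------------------------------------------
# serialization: long CSV of scores + JSON sidecar carrying truth and seed


def write_panel(panel: PanelDataset, csv_path, json_path=None) -> None:
    csv_path = Path(csv_path)
    if json_path is None:
        json_path = csv_path.with_suffix(".json")
    N, T = panel.scores.shape
    df = pd.DataFrame(
        {
            "individual": np.repeat(np.arange(N), T),
            "time": np.tile(np.arange(T), N),
            "score": panel.scores.ravel(),
        }
    )
    df.to_csv(csv_path, index=False, float_format="%.17g")
    meta = {
        "condition": asdict(panel.condition),
        "seed": panel.seed,
        "phi_true": [float(f"{v:.17g}") for v in panel.phi_true],
        "mu_true": [float(f"{v:.17g}") for v in panel.mu_true],
    }
    Path(json_path).write_text(json.dumps(meta, indent=1))


def read_panel(csv_path, json_path=None) -> PanelDataset:
    csv_path = Path(csv_path)
    if json_path is None:
        json_path = csv_path.with_suffix(".json")
    meta = json.loads(Path(json_path).read_text())
    cond = Condition(**meta["condition"])
    df = pd.read_csv(csv_path, float_precision="round_trip")
    scores = (
        df.sort_values(["individual", "time"])["score"]
        .to_numpy()
        .reshape(cond.N, cond.T)
    )
    return PanelDataset(
        scores=scores,
        phi_true=np.array(meta["phi_true"]),
        mu_true=np.array(meta["mu_true"]),
        condition=cond,
        seed=meta["seed"],
    )
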