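"""Frequentist estimators for the multilevel AR(1) model.

Two estimators are provided:

* ``fit_mle_fixed`` (MLE-F): every individual's series is fitted separately by
  exact Gaussian maximum likelihood, with the stationary initial term
  included, so the autocorrelation estimate is constrained to (-1, 1).
  Population summaries are plain averages of the per-individual estimates.

* ``fit_mle_random`` (MLE-R): a restricted-maximum-likelihood (REML) fit of
  the linear mixed model implied by the composite multilevel equation —
  response y_t (t = 2..T) regressed on y_{t-1} with a fixed intercept and
  slope plus uncorrelated per-individual random intercepts and slopes and a
  homogeneous residual SD.  Individual autocorrelations are predicted as
  fixed slope + BLUP of the random slope; these predictions are not
  constrained and may fall outside (-1, 1), which is tallied.

The REML fit is written directly on the profiled deviance: with variance
ratios lam = (sigma_u0^2, sigma_u1^2) / sigma_e^2, both the fixed effects
and the residual variance have closed forms, leaving a two-dimensional
bounded optimization.  Because the random-effect design equals the
fixed-effect design ([1, y_{t-1}]), everything reduces to per-individual
2x2 cross-product matrices, so one criterion evaluation is O(N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .datagen import PanelDataset

__all__ = [
    "SingleFit",
    "FixedModelFit",
    "RandomModelFit",
    "fit_ar1_single",
    "fit_mle_fixed",
    "fit_mle_random",
]

_PHI_EDGE = 1.0 - 1e-7


@dataclass
class SingleFit:
    """Exact-likelihood AR(1) fit for one series."""

    mu_hat: float
    phi_hat: float
    sigma_e_hat: float
    se_phi: float
    converged: bool
    interval_phi: tuple[float, float]


@dataclass
class FixedModelFit:
    """Aggregate of per-individual fits (fixed model).

    gamma01_hat is the mean of the converged phi estimates, se_gamma01 the
    mean of their standard errors, sigma_u1_hat their sample SD (n-1), and
    ci_gamma01 a t interval with df = N - 2.
    """

    per_individual: list
    gamma01_hat: float
    se_gamma01: float
    sigma_u1_hat: float
    ci_gamma01: tuple[float, float]
    n_nonconverged: int


@dataclass
class RandomModelFit:
    """REML mixed-model fit (random model)."""

    gamma01_hat: float
    se_gamma01: float
    gamma00_hat: float
    sigma_u1_hat: float
    sigma_u0_hat: float
    sigma_e_hat: float
    phi_individual: np.ndarray
    ci_gamma01: tuple[float, float]
    n_nonstationary: int
    converged: bool
    boundary: bool = False
    reml_criterion: float = float("nan")


# ---------------------------------------------------------------------------
# single-series exact stationary likelihood


def _suffstats(y: np.ndarray):
    y = np.asarray(y, dtype=float)
    T = y.size
    return (
        T,
        y[0],
        y[1:].sum(),
        y[:-1].sum(),
        (y[1:] ** 2).sum(),
        (y[:-1] ** 2).sum(),
        (y[1:] * y[:-1]).sum(),
    )


def _profile_pieces(phi, ss):
    """Closed-form mu_hat(phi) and minimized sum-of-squares S(phi)."""
    T, y1, a1, a0, q1, q0, cr = ss
    sd = a1 - phi * a0  # sum of d_t = y_t - phi*y_{t-1}
    sd2 = q1 - 2.0 * phi * cr + phi * phi * q0
    w1 = 1.0 - phi * phi
    w2 = 1.0 - phi
    denom = w1 + (T - 1) * w2 * w2
    mu = (w1 * y1 + w2 * sd) / denom
    S = (
        w1 * (y1 - mu) ** 2
        + sd2
        - 2.0 * mu * w2 * sd
        + (T - 1) * (mu * w2) ** 2
    )
    return mu, S


def _profile_deviance(phi, ss):
    T = ss[0]
    _, S = _profile_pieces(phi, ss)
    return T * np.log(S / T) - np.log1p(-phi * phi)


def _neg_loglik(theta, y):
    """-log L in (mu, z, log sigma) with phi = tanh(z); stationary term included."""
    mu, z, logs = theta
    phi = np.tanh(z)
    s2 = np.exp(2.0 * logs)
    T = y.size
    resid0 = y[0] - mu
    innov = y[1:] - mu - phi * (y[:-1] - mu)
    S = (1.0 - phi * phi) * resid0 * resid0 + (innov * innov).sum()
    return (
        T * logs
        - 0.5 * np.log1p(-phi * phi)
        + 0.5 * S / s2
        + 0.5 * T * np.log(2.0 * np.pi)
    )


def _hessian_fd(f, x, args=(), h=1e-4):
    x = np.asarray(x, dtype=float)
    k = x.size
    H = np.empty((k, k))
    hs = h * np.maximum(1.0, np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = hs[i]
            ej[j] = hs[j]
            fpp = f(x + ei + ej, *args)
            fpm = f(x + ei - ej, *args)
            fmp = f(x - ei + ej, *args)
            fmm = f(x - ei - ej, *args)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * hs[i] * hs[j])
    return H


def fit_ar1_single(series, alpha: float = 0.05) -> SingleFit:
    """Exact-likelihood AR(1) fit with the autocorrelation kept in (-1, 1).

    The likelihood includes the stationary density of the first observation,
    which keeps the optimum strictly inside the stationary region.  The
    profile deviance in phi is scanned on a coarse grid and polished with a
    bounded scalar minimizer; the SE of phi comes from the inverse observed
    information in the (mu, atanh(phi), log sigma) parameterization,
    delta-method-corrected back to the phi scale.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 3:
        raise ValueError("series must have at least 3 observations")
    if np.ptp(y) == 0 or y.std() == 0:
        raise ValueError("degenerate series")
    ss = _suffstats(y)

    grid = np.linspace(-_PHI_EDGE, _PHI_EDGE, 81)
    dev = _profile_deviance(grid, ss)
    i0 = int(np.argmin(dev))
    lo = grid[max(i0 - 1, 0)]
    hi = grid[min(i0 + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        _profile_deviance,
        bounds=(lo, hi),
        args=(ss,),
        method="bounded",
        options={"xatol": 1e-10},
    )
    phi_hat = float(res.x)
    mu_hat, S = _profile_pieces(phi_hat, ss)
    sigma_hat = float(np.sqrt(S / y.size))
    converged = bool(res.success) and abs(phi_hat) < 1

    se_phi = np.nan
    if converged:
        theta = np.array([mu_hat, np.arctanh(phi_hat), np.log(sigma_hat)])
        H = _hessian_fd(_neg_loglik, theta, args=(y,))
        try:
            cov = np.linalg.inv(H)
            var_z = cov[1, 1]
            if var_z <= 0 or not np.isfinite(var_z):
                converged = False
            else:
                # d phi / d z = 1 - phi^2
                se_phi = float(np.sqrt(var_z) * (1.0 - phi_hat * phi_hat))
        except np.linalg.LinAlgError:
            converged = False

    zq = stats.norm.ppf(1.0 - alpha / 2.0)
    if np.isfinite(se_phi):
        interval = (phi_hat - zq * se_phi, phi_hat + zq * se_phi)
    else:
        interval = (np.nan, np.nan)
    return SingleFit(
        mu_hat=float(mu_hat),
        phi_hat=phi_hat,
        sigma_e_hat=sigma_hat,
        se_phi=se_phi,
        converged=converged,
        interval_phi=interval,
    )


def fit_mle_fixed(panel: PanelDataset, alpha: float = 0.05) -> FixedModelFit:
    """Per-individual exact AR(1) fits aggregated into population summaries.

    Non-converged individuals are excluded from the aggregation and counted.
    The population CI uses a t quantile with df = N - 2, N being the number
    of usable individual fits.
    """
    fits = []
    for n in range(panel.N):
        try:
            fits.append(fit_ar1_single(panel.scores[n], alpha=alpha))
        except ValueError:
            fits.append(
                SingleFit(np.nan, np.nan, np.nan, np.nan, False, (np.nan, np.nan))
            )
    ok = [f for f in fits if f.converged]
    n_bad = len(fits) - len(ok)
    if not ok:
        raise ValueError("no usable fits")
    phis = np.array([f.phi_hat for f in ok])
    ses = np.array([f.se_phi for f in ok])
    gamma01_hat = float(phis.mean())
    se_gamma01 = float(ses.mean())
    sigma_u1_hat = float(phis.std(ddof=1)) if phis.size > 1 else 0.0
    n_use = len(ok)
    if n_use < 3:
        raise ValueError("need at least 3 usable individual fits for the CI")
    tq = stats.t.ppf(1.0 - alpha / 2.0, df=n_use - 2)
    ci = (gamma01_hat - tq * se_gamma01, gamma01_hat + tq * se_gamma01)
    return FixedModelFit(
        per_individual=fits,
        gamma01_hat=gamma01_hat,
        se_gamma01=se_gamma01,
        sigma_u1_hat=sigma_u1_hat,
        ci_gamma01=ci,
        n_nonconverged=n_bad,
    )


# ---------------------------------------------------------------------------
# REML for the random-intercept / random-slope mixed model


class _RemlWork:
    """Per-panel cross-products for the lagged-response mixed model.

    For individual n let U_n = [1, y_{t-1,n}] (m x 2, m = T-1) and
    y*_n = y_{t,n}.  With unit residual variance and variance ratios
    lam = (lam0, lam1), W_n = I + U_n diag(lam) U_n'.  All REML quantities
    reduce to A_n = U_n'U_n, c_n = U_n'y*_n and y*_n'y*_n.
    """

    def __init__(self, panel: PanelDataset):
        y = panel.scores
        N, T = y.shape
        x = y[:, :-1]
        z = y[:, 1:]
        m = T - 1
        self.N, self.m = N, m
        self.M = N * m
        self.a01 = x.sum(axis=1)
        self.a11 = (x * x).sum(axis=1)
        self.c0 = z.sum(axis=1)
        self.c1 = (x * z).sum(axis=1)
        self.yy = float((z * z).sum())

    def _bmat(self, theta):
        """Per-individual B = L K^{-1} L' and log|K| for D = L L'.

        theta is (lam0, lam1) for a diagonal D (uncorrelated effects) or a
        Cholesky triple (l0, l1, l2) with D = [[l0^2, l0*l1],
        [l0*l1, l1^2 + l2^2]] for a free intercept-slope covariance.
        """
        m, a01, a11 = self.m, self.a01, self.a11
        if len(theta) == 2:
            lam0 = max(float(theta[0]), 0.0)
            lam1 = max(float(theta[1]), 0.0)
            K00 = 1.0 + lam0 * m
            K11 = 1.0 + lam1 * a11
            detK = K00 * K11 - lam0 * lam1 * a01 * a01
            B00 = lam0 * K11 / detK
            B11 = lam1 * K00 / detK
            B01 = -lam0 * lam1 * a01 / detK
            return detK, B00, B01, B11
        l0 = max(float(theta[0]), 0.0)
        l1 = float(theta[1])
        l2 = max(float(theta[2]), 0.0)
        # K = I + L' A L with L = [[l0, 0], [l1, l2]]
        K00 = 1.0 + l0 * l0 * m + 2.0 * l0 * l1 * a01 + l1 * l1 * a11
        K01 = l2 * (l0 * a01 + l1 * a11)
        K11 = 1.0 + l2 * l2 * a11
        detK = K00 * K11 - K01 * K01
        # Kinv entries (dividing by detK), then B = L Kinv L'
        i00 = K11 / detK
        i01 = -K01 / detK
        i11 = K00 / detK
        B00 = l0 * l0 * i00
        B01 = l0 * (l1 * i00 + l2 * i01)
        B11 = l1 * l1 * i00 + 2.0 * l1 * l2 * i01 + l2 * l2 * i11
        return detK, B00, B01, B11

    def _pieces(self, theta):
        m, a01, a11 = self.m, self.a01, self.a11
        c0, c1 = self.c0, self.c1
        detK, B00, B01, B11 = self._bmat(theta)
        # AB = A @ B per individual (A = [[m, a01], [a01, a11]])
        AB00 = m * B00 + a01 * B01
        AB01 = m * B01 + a01 * B11
        AB10 = a01 * B00 + a11 * B01
        AB11 = a01 * B01 + a11 * B11
        X00 = float(np.sum(m - (AB00 * m + AB01 * a01)))
        X01 = float(np.sum(a01 - (AB00 * a01 + AB01 * a11)))
        X11 = float(np.sum(a11 - (AB10 * a01 + AB11 * a11)))
        Y0 = float(np.sum(c0 - (AB00 * c0 + AB01 * c1)))
        Y1 = float(np.sum(c1 - (AB10 * c0 + AB11 * c1)))
        ytWiy = self.yy - float(
            np.sum(B00 * c0 * c0 + 2.0 * B01 * c0 * c1 + B11 * c1 * c1)
        )
        B = (B00, B01, B11)
        AB = (AB00, AB01, AB10, AB11)
        return detK, B, AB, (X00, X01, X11), (Y0, Y1), ytWiy

    @staticmethod
    def _beta(X, Y):
        X00, X01, X11 = X
        detX = X00 * X11 - X01 * X01
        b0 = (X11 * Y[0] - X01 * Y[1]) / detX
        b1 = (X00 * Y[1] - X01 * Y[0]) / detX
        return detX, b0, b1

    def criterion(self, lam) -> float:
        """Profiled REML deviance (up to an additive constant)."""
        detK, _, _, X, Y, ytWiy = self._pieces(lam)
        if np.any(detK <= 0):
            return np.inf
        detX, b0, b1 = self._beta(X, Y)
        if detX <= 0:
            return np.inf
        rss = ytWiy - (b0 * Y[0] + b1 * Y[1])
        if rss <= 0:
            return np.inf
        dfr = self.M - 2
        return float(np.log(detK).sum() + np.log(detX) + dfr * np.log(rss / dfr))

    @staticmethod
    def _dmat(theta):
        """Random-effect covariance D (relative to sigma_e^2) from theta."""
        if len(theta) == 2:
            return max(theta[0], 0.0), 0.0, max(theta[1], 0.0)
        l0 = max(theta[0], 0.0)
        l1 = float(theta[1])
        l2 = max(theta[2], 0.0)
        return l0 * l0, l0 * l1, l1 * l1 + l2 * l2

    def solution(self, theta):
        detK, B, AB, X, Y, ytWiy = self._pieces(theta)
        detX, b0, b1 = self._beta(X, Y)
        beta = np.array([b0, b1])
        rss = ytWiy - (b0 * Y[0] + b1 * Y[1])
        dfr = self.M - 2
        s2 = rss / dfr
        X00, X01, X11 = X
        covb = s2 / detX * np.array([[X11, -X01], [-X01, X00]])
        # residual cross-products r = c - A beta, then U' W^{-1} r
        AB00, AB01, AB10, AB11 = AB
        cr0 = self.c0 - (self.m * b0 + self.a01 * b1)
        cr1 = self.c1 - (self.a01 * b0 + self.a11 * b1)
        uw0 = cr0 - (AB00 * cr0 + AB01 * cr1)
        uw1 = cr1 - (AB10 * cr0 + AB11 * cr1)
        D00, D01, D11 = self._dmat(theta)
        blup = np.column_stack(
            [D00 * uw0 + D01 * uw1, D01 * uw0 + D11 * uw1]
        )
        return beta, covb, s2, blup, (D00, D01, D11)


def fit_mle_random(
    panel: PanelDataset,
    alpha: float = 0.05,
    correlation: str = "none",
) -> RandomModelFit:
    """REML fit of the random-intercept / random-slope lagged regression.

    With ``correlation="none"`` (default) the random intercept and random
    slope are uncorrelated, matching a multilevel model that declares no
    covariance between them; ``correlation="free"`` additionally estimates
    their covariance (the default of common mixed-model software).
    Individual autocorrelation predictions are fixed slope + BLUP of the
    random slope; the count with absolute value above 1 is recorded as
    ``n_nonstationary``.
    """
    if correlation not in ("none", "free"):
        raise ValueError("correlation must be 'none' or 'free'")
    if panel.N < 2:
        raise ValueError("random model needs at least 2 individuals")
    if panel.T < 3:
        raise ValueError("random model needs at least 3 time points")
    work = _RemlWork(panel)

    # the profiled surface is in practice unimodal; extra starts are a
    # safety net taken only when the first one fails
    starts = [(0.5, 0.05), (0.05, 0.5), (1e-6, 1e-6)]
    best = None
    for k, x0 in enumerate(starts):
        res = optimize.minimize(
            work.criterion,
            x0=np.array(x0),
            method="L-BFGS-B",
            bounds=[(0.0, 1e6), (0.0, 1e6)],
        )
        if best is None or res.fun < best.fun:
            best = res
        if k == 0 and res.success and np.isfinite(res.fun):
            break
    theta = np.maximum(best.x, 0.0)
    if correlation == "free":
        x0 = np.array([np.sqrt(theta[0]), 0.0, np.sqrt(theta[1])])
        res = optimize.minimize(
            work.criterion,
            x0=x0,
            method="L-BFGS-B",
            bounds=[(0.0, 1e3), (-1e3, 1e3), (0.0, 1e3)],
        )
        if res.fun <= best.fun + 1e-9:
            best = res
            theta = res.x
    converged = bool(np.isfinite(best.fun))

    beta, covb, s2, blup, D = work.solution(theta)
    phi_ind = beta[1] + blup[:, 1]
    se_g01 = float(np.sqrt(covb[1, 1]))
    n_use = panel.N
    tq = stats.t.ppf(1.0 - alpha / 2.0, df=max(n_use - 2, 1))
    ci = (beta[1] - tq * se_g01, beta[1] + tq * se_g01)
    return RandomModelFit(
        gamma01_hat=float(beta[1]),
        se_gamma01=se_g01,
        gamma00_hat=float(beta[0]),
        sigma_u1_hat=float(np.sqrt(D[2] * s2)),
        sigma_u0_hat=float(np.sqrt(D[0] * s2)),
        sigma_e_hat=float(np.sqrt(s2)),
        phi_individual=phi_ind,
        ci_gamma01=ci,
        n_nonstationary=int(np.sum(np.abs(phi_ind) > 1)),
        converged=converged,
        boundary=bool(min(D[0], D[2]) <= 1e-10),
        reml_criterion=float(best.fun),
    )
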