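"""Statistical layer for translocation times.

Three pieces of machinery:

* the Moyal distribution — the right-skewed location-scale family that
  models the randomness of the translocation time tau.  With location ``m``
  (the density peak) and scale ``s > 0``,

      psi(tau) = 1/(s*sqrt(2*pi)) * exp(-((tau-m)/s + exp(-(tau-m)/s)) / 2)

  and the moments relate to the parameters through
  ``mean = m + s*(ln 2 + gamma)`` and ``sd = s*pi/sqrt(2)`` with gamma the
  Euler-Mascheroni constant.  Fitting is by maximum likelihood, moment
  initialised; goodness of fit by Cramer-von Mises or Anderson-Darling
  statistics with parametric-bootstrap p-values (the composite-hypothesis
  critical values are not tabulated for this family).

* the power law ``mean_tau(L) = a + b * L**xi`` linking the mean
  translocation time to the membrane thickness L.

* ordinary least squares on the design (1, phi_cis, phi_trans,
  phi_cis/phi_trans) for the mean translocation time, and for log(sd), as
  functions of the pore diameters at fixed L.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import integrate, optimize, special

#: Euler-Mascheroni constant, as used in the moment/parameter conversions.
EULER_GAMMA = float(np.euler_gamma)

_LN2 = math.log(2.0)
_HALF_LOG_2PI = 0.5 * math.log(2.0 * math.pi)

CRAMER_VON_MISES = "cramer_von_mises"
ANDERSON_DARLING = "anderson_darling"


class FitError(RuntimeError):
    """Raised when an estimation routine cannot produce a valid fit."""


# ---------------------------------------------------------------------------
# Moyal density, distribution and conversions
# ---------------------------------------------------------------------------

def moyal_logpdf(tau, m: float, s: float):
    """Log-density of the Moyal distribution (stable far into both tails)."""
    if s <= 0:
        raise ValueError(f"scale s must be > 0, got {s}")
    z = (np.asarray(tau, dtype=float) - m) / s
    return -math.log(s) - _HALF_LOG_2PI - 0.5 * (np.exp(-z) + z)


def moyal_pdf(tau, m: float, s: float):
    """Moyal probability density psi(tau; m, s)."""
    return np.exp(moyal_logpdf(tau, m, s))


def moyal_cdf(tau, m: float, s: float):
    """Moyal distribution function, ``erfc(exp(-z/2) / sqrt(2))``."""
    if s <= 0:
        raise ValueError(f"scale s must be > 0, got {s}")
    z = (np.asarray(tau, dtype=float) - m) / s
    return special.erfc(np.exp(-z / 2.0) / math.sqrt(2.0))


def sample_moyal(n: int, m: float, s: float, rng: np.random.Generator):
    """Draw Moyal variates: if X ~ N(0,1) then -2*ln|X| is standard Moyal."""
    if s <= 0:
        raise ValueError(f"scale s must be > 0, got {s}")
    x = np.abs(rng.standard_normal(n))
    x = np.where(x == 0.0, np.finfo(float).tiny, x)
    return m - 2.0 * s * np.log(x)


def moyal_params_from_moments(tau_mean: float, sigma: float) -> tuple[float, float]:
    """(mean, sd) -> (m, s): ``s = sigma*sqrt(2)/pi``, ``m = mean - s*(ln2 + gamma)``."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    s = sigma * math.sqrt(2.0) / math.pi
    m = tau_mean - s * (_LN2 + EULER_GAMMA)
    return m, s


def moyal_moments_from_params(m: float, s: float) -> tuple[float, float]:
    """(m, s) -> (mean, sd), the algebraic inverse of the conversion above."""
    if s <= 0:
        raise ValueError(f"scale s must be > 0, got {s}")
    return m + s * (_LN2 + EULER_GAMMA), s * math.pi / math.sqrt(2.0)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting and goodness of fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GofResult:
    which: str
    statistic: float
    p_value: float | None
    n_bootstrap: int


@dataclass(frozen=True)
class MoyalFit:
    """Fitted Moyal parameters in both parameterizations."""

    m: float
    s: float
    tau_mean: float
    sigma: float
    n: int
    loglik: float
    gof: GofResult | None = None


def _moyal_mle(x: np.ndarray) -> tuple[float, float, float]:
    m0, s0 = moyal_params_from_moments(float(np.mean(x)), float(np.std(x, ddof=1)))

    def nll_grad(theta):
        m, log_s = theta
        s = math.exp(log_s)
        z = (x - m) / s
        ez = np.exp(-z)
        nll = x.size * (log_s + _HALF_LOG_2PI) + 0.5 * np.sum(ez + z)
        d_dz = 0.5 * (1.0 - ez)
        g_m = float(np.sum(d_dz) * (-1.0 / s))
        g_logs = float(x.size + np.sum(d_dz * (-z)))
        return float(nll), np.array([g_m, g_logs])

    res = optimize.minimize(nll_grad, x0=np.array([m0, math.log(s0)]), jac=True, method="BFGS")
    if not res.success:
        # BFGS can stall on a flat curvature; polish with Nelder-Mead before giving up
        res = optimize.minimize(lambda t: nll_grad(t)[0], x0=res.x, method="Nelder-Mead")
        if not res.success:
            raise FitError(f"Moyal MLE did not converge: {res.message}")
    m_hat, log_s_hat = res.x
    return float(m_hat), float(math.exp(log_s_hat)), float(-res.fun)


def fit_moyal(samples, gof: str | None = None, n_bootstrap: int = 500, rng=None) -> MoyalFit:
    """Maximum-likelihood Moyal fit, moment-initialised.

    Parameters
    ----------
    samples : array-like
        At least 10 observations with positive variance.
    gof : str, optional
        ``"cramer_von_mises"`` or ``"anderson_darling"``; when given, a
        bootstrap goodness-of-fit test is attached to the returned fit.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 10:
        raise FitError(f"need at least 10 samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise FitError("samples contain non-finite values")
    if np.std(x) == 0.0:
        raise FitError("samples have zero variance")
    m_hat, s_hat, loglik = _moyal_mle(x)
    mean, sd = moyal_moments_from_params(m_hat, s_hat)
    fit = MoyalFit(m=m_hat, s=s_hat, tau_mean=mean, sigma=sd, n=x.size, loglik=loglik)
    if gof is not None:
        g = gof_test(x, fit, which=gof, n_bootstrap=n_bootstrap, rng=rng)
        fit = MoyalFit(m=m_hat, s=s_hat, tau_mean=mean, sigma=sd, n=x.size, loglik=loglik, gof=g)
    return fit


def _clip_probs(u: np.ndarray) -> np.ndarray:
    tiny = 1e-12
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        warnings.warn("fitted CDF reached 0 or 1 at a sample point; clipping", RuntimeWarning)
        u = np.clip(u, tiny, 1.0 - tiny)
    return u


def cramer_von_mises_statistic(u) -> float:
    """W^2 from sorted probability-integral-transformed values ``u``.

    ``W^2 = 1/(12n) + sum_i (u_(i) - (2i-1)/(2n))^2``.
    """
    u = np.sort(np.asarray(u, dtype=float))
    n = u.size
    i = np.arange(1, n + 1)
    return float(1.0 / (12.0 * n) + np.sum((u - (2.0 * i - 1.0) / (2.0 * n)) ** 2))


def anderson_darling_statistic(u) -> float:
    """A^2 from sorted probability-integral-transformed values ``u``.

    ``A^2 = -n - (1/n) * sum_i (2i-1) * [ln u_(i) + ln(1 - u_(n+1-i))]``.
    """
    u = _clip_probs(np.sort(np.asarray(u, dtype=float)))
    n = u.size
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2.0 * i - 1.0) * (np.log(u) + np.log1p(-u[::-1]))))


_GOF_STATISTICS = {
    CRAMER_VON_MISES: cramer_von_mises_statistic,
    ANDERSON_DARLING: anderson_darling_statistic,
}


def gof_test(
    samples,
    fit: MoyalFit,
    which: str = CRAMER_VON_MISES,
    n_bootstrap: int = 500,
    rng=None,
) -> GofResult:
    """Goodness of fit of a Moyal MLE, with a parametric-bootstrap p-value.

    Each bootstrap replicate redraws ``n`` samples from the fitted Moyal and
    *refits* before computing the statistic, so the null distribution
    accounts for parameter estimation.  ``n_bootstrap = 0`` returns the
    statistic alone.
    """
    if which not in _GOF_STATISTICS:
        raise ValueError(f"which must be one of {sorted(_GOF_STATISTICS)}")
    stat_fn = _GOF_STATISTICS[which]
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 10:
        raise FitError(f"need at least 10 samples, got {x.size}")
    observed = stat_fn(_clip_probs(moyal_cdf(x, fit.m, fit.s)))
    if n_bootstrap == 0:
        return GofResult(which, observed, None, 0)
    rng = np.random.default_rng(rng)
    exceed = 0
    for _ in range(n_bootstrap):
        xb = sample_moyal(x.size, fit.m, fit.s, rng)
        try:
            mb, sb, _ = _moyal_mle(xb)
        except FitError:
            exceed += 1  # count non-convergent replicates against the null
            continue
        if stat_fn(_clip_probs(moyal_cdf(xb, mb, sb))) >= observed:
            exceed += 1
    p = (1.0 + exceed) / (n_bootstrap + 1.0)
    return GofResult(which, observed, p, n_bootstrap)


def moyal_moments_by_quadrature(m: float, s: float) -> tuple[float, float]:
    """Mean and sd of Moyal(m, s) by adaptive quadrature (slow oracle path)."""
    mean_z, _ = integrate.quad(lambda z: z * math.exp(-0.5 * (math.exp(-z) + z)) / math.sqrt(2 * math.pi), -30, 300, limit=400)
    m2_z, _ = integrate.quad(lambda z: z * z * math.exp(-0.5 * (math.exp(-z) + z)) / math.sqrt(2 * math.pi), -30, 300, limit=400)
    sd_z = math.sqrt(m2_z - mean_z**2)
    return m + s * mean_z, s * sd_z


# ---------------------------------------------------------------------------
# Power law: mean_tau = a + b * L**xi
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerLawFit:
    a: float
    b: float
    xi: float
    residual_sse: float
    n_points: int

    def predict(self, L):
        return self.a + self.b * np.asarray(L, dtype=float) ** self.xi


def _profile_sse(xi: float, L: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    X = np.column_stack([np.ones_like(L), L**xi])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def fit_power_law(L_values, tau_means, xi_grid=None) -> PowerLawFit:
    """Least-squares fit of ``a + b * L**xi``.

    The exponent is initialised from a grid (default ``[0.5, 3]`` in steps
    of 0.025, ties resolved toward the smaller exponent) with ``(a, b)``
    profiled linearly at each trial ``xi``, then polished jointly.
    """
    L = np.asarray(L_values, dtype=float).ravel()
    y = np.asarray(tau_means, dtype=float).ravel()
    if L.size != y.size:
        raise ValueError("L_values and tau_means must have equal length")
    if np.unique(L).size < 4:
        raise FitError("need at least 4 distinct L values for a 3-parameter fit")
    if not (np.all(np.isfinite(y)) and np.all(L > 0)):
        raise FitError("inputs must be finite with positive L")
    if xi_grid is None:
        xi_grid = np.arange(0.5, 3.0 + 1e-9, 0.025)
    sses = np.array([_profile_sse(xi, L, y)[2] for xi in xi_grid])
    k = int(np.argmin(sses))  # first minimum -> smaller xi on ties
    lo = xi_grid[max(k - 1, 0)]
    hi = xi_grid[min(k + 1, len(xi_grid) - 1)]
    res = optimize.minimize_scalar(
        lambda xi: _profile_sse(xi, L, y)[2], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    xi0 = float(res.x)
    a0, b0, _ = _profile_sse(xi0, L, y)
    polish = optimize.least_squares(
        lambda t: t[0] + t[1] * L ** t[2] - y, x0=np.array([a0, b0, xi0]), method="lm",
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    a, b, xi = (float(v) for v in polish.x)
    sse = float(np.sum(polish.fun**2))
    if not np.isfinite(sse):
        raise FitError("power-law fit did not converge")
    return PowerLawFit(a=a, b=b, xi=xi, residual_sse=sse, n_points=int(L.size))


# ---------------------------------------------------------------------------
# Diameter regressions at fixed L
# ---------------------------------------------------------------------------

TAU_MEAN = "TAU_MEAN"
LOG_SIGMA = "LOG_SIGMA"

DESIGN_LABELS = ("intercept", "phi_cis", "phi_trans", "phi_cis/phi_trans")


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of a response on (1, phi_cis, phi_trans, phi_cis/phi_trans).

    ``model_std_error`` is the residual scale ``sqrt(SSE / (n - 4))`` and
    ``cov`` its ratio to the mean response (coefficient of variation).
    """

    coefficients: tuple[float, float, float, float]
    p_values: tuple[float, float, float, float]
    r_squared: float
    model_std_error: float
    cov: float
    design_labels: tuple[str, ...]
    response: str
    n: int

    def predict(self, phi_cis, phi_trans):
        b = self.coefficients
        pc = np.asarray(phi_cis, dtype=float)
        pt = np.asarray(phi_trans, dtype=float)
        return b[0] + b[1] * pc + b[2] * pt + b[3] * pc / pt


def fit_diameter_regression(
    summary: pd.DataFrame, response: str = TAU_MEAN, log_base: str = "e"
) -> RegressionFit:
    """Fit the diameter regression at one membrane thickness.

    ``summary`` needs columns ``phi_cis``, ``phi_trans`` and ``tau_mean``
    (for ``response=TAU_MEAN``) or ``tau_sd`` (for ``response=LOG_SIGMA``,
    modelling ``log(sd)``; natural log by default, base 10 via
    ``log_base="10"``).
    """
    if response not in (TAU_MEAN, LOG_SIGMA):
        raise ValueError(f"response must be {TAU_MEAN} or {LOG_SIGMA}")
    df = summary
    for col in ("phi_cis", "phi_trans"):
        if col not in df.columns:
            raise ValueError(f"summary is missing required column {col!r}")
        if np.any(df[col].to_numpy() <= 0):
            raise ValueError(f"column {col!r} must be positive")
    if len(df) < 6:
        raise FitError(f"need at least 6 rows, got {len(df)}")
    if response == TAU_MEAN:
        y = df["tau_mean"].to_numpy(dtype=float)
    else:
        sd = df["tau_sd"].to_numpy(dtype=float)
        if np.any(sd <= 0):
            raise FitError("tau_sd must be positive to take logarithms")
        y = np.log(sd) if log_base == "e" else np.log10(sd)
    pc = df["phi_cis"].to_numpy(dtype=float)
    pt = df["phi_trans"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(pc), pc, pt, pc / pt])
    if np.linalg.matrix_rank(X) < 4:
        degenerate = [
            lab
            for lab, col in zip(DESIGN_LABELS[1:], X.T[1:])
            if np.unique(col).size == 1
        ]
        raise FitError(
            "rank-deficient design; collinear columns: "
            + (", ".join(degenerate) if degenerate else "phi_cis/phi_trans combination")
        )
    with warnings.catch_warnings():
        # a constant response makes R^2 and t statistics 0/0; handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        model = sm.OLS(y, X).fit()
        n = len(df)
        sse = float(np.sum(model.resid**2))
        mse_model = math.sqrt(sse / (n - 4))
        r2 = float(model.rsquared)
        pvalues = model.pvalues
    if not np.isfinite(r2):  # constant response: zero total variation
        r2 = 0.0
    mean_y = float(np.mean(y))
    pvals = tuple(float(p) if np.isfinite(p) else 0.0 for p in pvalues)
    return RegressionFit(
        coefficients=tuple(float(c) for c in model.params),
        p_values=pvals,
        r_squared=r2,
        model_std_error=mse_model,
        cov=mse_model / mean_y if mean_y != 0 else math.inf,
        design_labels=DESIGN_LABELS,
        response=response,
        n=n,
    )
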