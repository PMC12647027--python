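"""Comparative statistical battery for waste indicators.

Implements the validation toolkit used to compare a raw generation rate with
a complexity-adjusted index measured on the same institutions:

* Shapiro-Wilk normality gatekeeping,
* a two-sided variance-ratio F-test,
* Spearman rank correlation,
* Fisher z comparison of two correlations (independent form) and Steiger's
  z for two dependent overlapping correlations,
* Huber M-estimation robust regression (IRLS) with residual diagnostics.

All tests are two-sided and return plain result containers that serialize
to JSON.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.robust import norms

__all__ = [
    "TestResult",
    "CorrelationResult",
    "RegressionResult",
    "ResidualDiagnostics",
    "shapiro_wilk",
    "variance_f_test",
    "spearman",
    "fisher_z_compare",
    "steiger_compare_dependent",
    "huber_regression",
    "residual_diagnostics",
]

HUBER_C = 1.345  # 95% Gaussian efficiency
BIWEIGHT_C = 4.685


@dataclass(frozen=True)
class TestResult:
    """A scalar hypothesis test: statistic, degrees of freedom, p-value."""

    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    test_name: str
    tails: str = "two-sided"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p_value must lie in [0, 1]")

    def to_dict(self) -> dict:
        df = list(self.df) if isinstance(self.df, tuple) else self.df
        return {
            "statistic": self.statistic,
            "df": df,
            "p_value": self.p_value,
            "test_name": self.test_name,
            "tails": self.tails,
        }


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation with its sample size and p-value."""

    rho: float
    n: int
    p_value: float

    def __post_init__(self) -> None:
        if abs(self.rho) > 1 + 1e-12:
            raise ValueError("|rho| must be <= 1")

    def to_dict(self) -> dict:
        return {"rho": self.rho, "n": self.n, "p_value": self.p_value}


@dataclass(frozen=True)
class RegressionResult:
    """Robust-regression fit: coefficients, uncertainties and residuals.

    ``params`` includes the intercept under the name ``const``; ``fitted +
    resid`` reconstructs the observed response exactly.
    """

    params: pd.Series
    bse: pd.Series
    p_values: pd.Series
    resid: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    scale: float
    n_iter: int
    converged: bool
    nobs: int

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "p_values": self.p_values.to_dict(),
            "scale": self.scale,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "nobs": self.nobs,
        }


@dataclass(frozen=True)
class ResidualDiagnostics:
    """Residual summary of a robust fit, including a heteroscedasticity cue."""

    fitted: np.ndarray = field(repr=False)
    resid: np.ndarray = field(repr=False)
    residual_sd: float
    spread_slope: float  # OLS slope of |residual| on fitted values

    def to_dict(self) -> dict:
        return {"residual_sd": self.residual_sd, "spread_slope": self.spread_slope}


def shapiro_wilk(values) -> TestResult:
    """Shapiro-Wilk W normality test (3 <= n <= 5000).

    Delegates the W statistic and Royston p-value to scipy; constant samples
    (zero variance) are rejected explicitly since W is undefined there.
    """
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    w, p = scipy.stats.shapiro(x)
    return TestResult(float(w), None, float(p), "shapiro_wilk")


def variance_f_test(x, y) -> TestResult:
    """Two-sided F-test of equal variances, F = s_x^2 / s_y^2.

    p = 2 * min(P(F <= f), P(F >= f)) capped at 1, with (n_x - 1, n_y - 1)
    degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("variance F-test requires >= 2 points per sample")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 or vy == 0:
        raise ValueError("variance F-test undefined for a zero-variance sample")
    f = vx / vy
    dfn, dfd = x.size - 1, y.size - 1
    dist = scipy.stats.f(dfn, dfd)
    p = min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f)))
    return TestResult(float(f), (float(dfn), float(dfd)), float(p), "variance_f_test")


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation: Pearson on average ranks, t-approximation p.

    Ties receive average ranks; the p-value uses the t distribution with
    n - 2 degrees of freedom.  Constant inputs raise (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("Spearman correlation requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho undefined for a constant vector")
    rho, p = scipy.stats.spearmanr(x, y)
    return CorrelationResult(float(rho), int(x.size), float(p))


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> TestResult:
    """Compare two correlations from independent samples via Fisher's z.

    ``Z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    two-sided standard-normal p-value.  Note the independent-samples form is
    an approximation when both correlations come from the same sample; see
    :func:`steiger_compare_dependent` for that case.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1 (Fisher z infinite at |r| = 1)")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("Fisher z comparison requires n > 3 in both samples")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return TestResult(float(z), None, float(min(p, 1.0)), "fisher_z_compare")


def steiger_compare_dependent(
    r_1c: float, r_2c: float, r_12: float, n: int
) -> TestResult:
    """Steiger's z for two dependent correlations sharing one variable.

    Compares corr(x1, c) with corr(x2, c) measured on one sample of size
    ``n`` where the predictors are themselves correlated ``r_12``
    (Steiger 1980, with the Dunn-Clark pooled-correlation refinement):

    ``Z = (z1 - z2) * sqrt((n - 3) / (2 * (1 - r_12) * h))`` where
    ``rbar = (r_1c + r_2c)/2``, ``f = (1 - r_12) / (2 * (1 - rbar^2))``
    (capped at 1) and ``h = (1 - f * rbar^2) / (1 - rbar^2)``.
    """
    for r in (r_1c, r_2c, r_12):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1")
    if n <= 4:
        raise ValueError("Steiger comparison requires n > 4")
    R = np.array([[1.0, r_12, r_1c], [r_12, 1.0, r_2c], [r_1c, r_2c, 1.0]])
    if np.linalg.det(R) <= 0:
        raise ValueError("infeasible correlation triple (non-PSD correlation matrix)")
    z1, z2 = math.atanh(r_1c), math.atanh(r_2c)
    rbar = (r_1c + r_2c) / 2.0
    f = min(1.0, (1.0 - r_12) / (2.0 * (1.0 - rbar**2)))
    h = (1.0 - f * rbar**2) / (1.0 - rbar**2)
    z = (z1 - z2) * math.sqrt((n - 3) / (2.0 * (1.0 - r_12) * h))
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return TestResult(float(z), None, float(min(p, 1.0)), "steiger_compare_dependent")


def _as_design(design) -> tuple[np.ndarray, list[str]]:
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i + 1}" for i in range(X.shape[1])]
    return X, names


def huber_regression(
    design,
    response,
    tuning_c: float = HUBER_C,
    max_iter: int = 50,
    tol: float = 1e-8,
    weight_function: str = "huber",
) -> RegressionResult:
    """Robust linear regression by iteratively reweighted least squares.

    ``design`` holds the predictor columns (an intercept is added and
    reported as ``const``).  Huber weights with ``tuning_c = 1.345`` by
    default (``weight_function="bisquare"`` switches to Tukey's biweight,
    conventional c = 4.685); the scale is re-estimated each iteration by the
    normalized median absolute deviation of the residuals, iterating until
    the maximum coefficient change falls below ``tol`` or ``max_iter`` is
    reached.  Standard errors come from the asymptotic sandwich covariance
    of the M-estimator.  Non-convergence sets ``converged=False`` and emits
    a warning, never a silent result.
    """
    X, names = _as_design(design)
    y = np.asarray(response, dtype=float)
    if y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("design and response shapes are inconsistent")
    k = X.shape[1]
    if y.size <= k + 1:
        raise ValueError("need n > number of predictors + 1")
    exog = np.column_stack([np.ones(y.size), X])
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError("rank-deficient design matrix")
    names = ["const", *names]

    # A perfect linear fit collapses the MAD scale to zero; return the exact
    # least-squares solution directly in that degenerate case.
    beta_ls, *_ = np.linalg.lstsq(exog, y, rcond=None)
    resid_ls = y - exog @ beta_ls
    y_scale = max(1.0, float(np.abs(y).max()))
    if np.abs(resid_ls).max() <= 1e-10 * y_scale:
        zero = pd.Series(np.zeros(len(names)), index=names)
        return RegressionResult(
            params=pd.Series(beta_ls, index=names),
            bse=zero,
            p_values=pd.Series(np.full(len(names), np.nan), index=names),
            resid=resid_ls,
            fitted=exog @ beta_ls,
            scale=0.0,
            n_iter=0,
            converged=True,
            nobs=int(y.size),
        )

    if weight_function == "huber":
        M = norms.HuberT(t=tuning_c)
    elif weight_function in ("bisquare", "biweight", "tukey"):
        M = norms.TukeyBiweight(c=tuning_c if tuning_c != HUBER_C else BIWEIGHT_C)
    else:
        raise ValueError(f"unknown weight_function: {weight_function!r}")

    model = sm.RLM(y, exog, M=M)
    fit = model.fit(
        maxiter=max_iter, tol=tol, conv="coefs", scale_est="mad", update_scale=True
    )
    n_iter = int(fit.fit_history.get("iteration", 0))
    converged = n_iter < max_iter
    if not converged:
        warnings.warn(
            f"Huber IRLS did not converge within {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return RegressionResult(
        params=pd.Series(fit.params, index=names),
        bse=pd.Series(fit.bse, index=names),
        p_values=pd.Series(fit.pvalues, index=names),
        resid=np.asarray(fit.resid),
        fitted=np.asarray(fit.fittedvalues),
        scale=float(fit.scale),
        n_iter=n_iter,
        converged=bool(converged),
        nobs=int(y.size),
    )


def residual_diagnostics(result: RegressionResult) -> ResidualDiagnostics:
    """Residual SD and a spread-versus-fitted slope as a heteroscedasticity cue.

    The slope is the OLS coefficient of |residual| on the fitted values; a
    value near zero indicates homoscedastic spread.
    """
    fitted = result.fitted
    resid = result.resid
    sd = float(resid.std(ddof=1)) if resid.size > 1 else 0.0
    if resid.size > 2 and np.ptp(fitted) > 0:
        slope = float(np.polyfit(fitted, np.abs(resid), 1)[0])
    else:
        slope = 0.0
    return ResidualDiagnostics(fitted=fitted, resid=resid, residual_sd=sd, spread_slope=slope)
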