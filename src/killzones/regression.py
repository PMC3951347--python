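"""Percentile-on-habitat regression with spatially autocorrelated errors.

The response is the kill-occurrence percentile (0-100) of a class's KDE
surface at each of that class's kill sites; the design holds the
standardized habitat covariates.  Errors follow a Gaussian process with
an exponential covariogram plus nugget,

    Sigma = tau^2 I + sigma^2 * exp(-d / phi),

fitted by REML: the overall scale and the regression coefficients are
profiled out and the optimizer works over the nugget proportion
``alpha = tau^2 / (tau^2 + sigma^2)`` in [0, 1] and log range phi, from
several starts.  ``alpha = 1`` is on the boundary, so independent errors
(ordinary least squares) are exactly nested and recovered when the data
carry no spatial structure.

Model reduction follows the "standard error overlaps zero" rule: every
non-intercept term with |beta| <= se is removed and the reduced design
refitted (a z-based rule at 1.96 is available as an option).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from scipy.spatial.distance import pdist, squareform

from .errors import CollinearityError, FitFailureError
from .habitat import HabitatMatrix

__all__ = [
    "RegressionResult",
    "DiagnosticsReport",
    "reml_loglik",
    "fit_gls",
    "diagnostics",
    "drop_and_refit",
    "effect_per_unit",
]

_FAMILIES = {
    "exponential": lambda d, phi: np.exp(-d / phi),
    "gaussian": lambda d, phi: np.exp(-((d / phi) ** 2)),
    "spherical": lambda d, phi: np.where(
        d < phi, 1 - 1.5 * (d / phi) + 0.5 * (d / phi) ** 3, 0.0
    ),
}


@dataclass
class RegressionResult:
    """Fitted spatial GLS model for one prey class."""

    params: pd.Series  # const + standardized covariates
    se: pd.Series
    cov_params: dict  # tau2 (nugget), sigma2 (partial sill), phi (range, m)
    loglik: float  # REML log-likelihood at the optimum
    residuals: np.ndarray
    fitted: np.ndarray
    class_label: str = "generic"
    removed: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def terms(self) -> list[str]:
        return list(self.params.index)


@dataclass
class DiagnosticsReport:
    normality_stat: float
    normality_p: float
    het_stat: float
    het_p: float


def _design(X: HabitatMatrix | pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, HabitatMatrix):
        df = X.data
    elif isinstance(X, pd.DataFrame):
        df = X
    else:
        arr = np.asarray(X, dtype=float)
        df = pd.DataFrame(arr, columns=[f"x{j}" for j in range(arr.shape[1])])
    names = ["const"] + list(df.columns)
    mat = np.column_stack([np.ones(len(df)), df.to_numpy(dtype=float)])
    return mat, names


def reml_loglik(
    y: np.ndarray,
    Xmat: np.ndarray,
    dists: np.ndarray,
    tau2: float,
    sigma2: float,
    phi: float,
    family: str = "exponential",
) -> float:
    """Restricted log-likelihood at fixed covariance parameters, with the
    GLS coefficient profile:

        l = -1/2 [ log|Sigma| + log|X' Sigma^-1 X| + r' Sigma^-1 r
                   + (n - p) log 2 pi ],   r = y - X beta_GLS.

    ``dists`` is the dense inter-site distance matrix.
    """
    n, p = Xmat.shape
    Sigma = tau2 * np.eye(n) + sigma2 * _FAMILIES[family](dists, phi)
    try:
        L = linalg.cholesky(Sigma, lower=True)
    except linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.log(np.diag(L)).sum()
    Xi = linalg.solve_triangular(L, Xmat, lower=True)
    yi = linalg.solve_triangular(L, y, lower=True)
    XtX = Xi.T @ Xi
    sign, logdet_xtx = np.linalg.slogdet(XtX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtX, Xi.T @ yi)
    r = yi - Xi @ beta
    return float(-0.5 * (logdet + logdet_xtx + r @ r + (n - p) * np.log(2 * np.pi)))


def _profiled_negloglik(
    alpha: float, log_phi: float, y: np.ndarray, Xmat: np.ndarray, dists: np.ndarray,
    family: str,
) -> float:
    """REML criterion with the overall variance scale s^2 profiled out:
    Sigma = s^2 (alpha I + (1 - alpha) R(phi))."""
    n, p = Xmat.shape
    V = alpha * np.eye(n) + (1 - alpha) * _FAMILIES[family](dists, np.exp(log_phi))
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        return np.inf
    logdetV = 2.0 * np.log(np.diag(L)).sum()
    Xi = linalg.solve_triangular(L, Xmat, lower=True)
    yi = linalg.solve_triangular(L, y, lower=True)
    XtX = Xi.T @ Xi
    sign, logdet_xtx = np.linalg.slogdet(XtX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtX, Xi.T @ yi)
    r = yi - Xi @ beta
    q = float(r @ r)
    if q <= 0:
        return np.inf
    s2 = q / (n - p)
    return 0.5 * (
        (n - p) * (np.log(s2) + 1 + np.log(2 * np.pi)) + logdetV + logdet_xtx
    )


def fit_gls(
    y: np.ndarray,
    X: HabitatMatrix | pd.DataFrame | np.ndarray,
    coords: np.ndarray,
    init: dict | None = None,
    seed: int = 0,
    family: str = "exponential",
    class_label: str = "generic",
) -> RegressionResult:
    """REML fit of the spatial linear model.

    Optimizes (nugget proportion, log range) by L-BFGS-B from multiple
    seeded starts over a log-spaced range grid, with the scale and the
    coefficients profiled out; standard errors come from the inverse
    information of the profiled GLS coefficients at the optimum.  When
    the restricted likelihood of independent errors ties the optimum
    (within 1e-8), the independent-error solution is preferred, making
    the OLS reduction exact.
    """
    y = np.asarray(y, dtype=float).ravel()
    coords = np.asarray(coords, dtype=float)
    Xmat, names = _design(X)
    n, p = Xmat.shape
    if not (len(y) == n == coords.shape[0]):
        raise ValueError("y, X and coords must have aligned rows")
    if n <= p + 3:
        raise ValueError("too few sites for the number of covariates")
    if family not in _FAMILIES:
        raise ValueError(f"unknown covariance family {family!r}")
    if np.linalg.cond(Xmat) > 1e10:
        raise CollinearityError("design matrix is numerically singular")

    dists = squareform(pdist(coords))
    dmax = float(dists.max())
    rng = np.random.default_rng(seed)

    def obj(theta: np.ndarray) -> float:
        return _profiled_negloglik(theta[0], theta[1], y, Xmat, dists, family)

    starts = [(0.5, np.log(0.15 * dmax)), (0.2, np.log(0.4 * dmax)), (0.9, np.log(0.05 * dmax))]
    if init is not None:
        tot = init.get("tau2", 0.5) + init.get("sigma2", 0.5)
        starts.insert(0, (init.get("tau2", 0.5) / max(tot, 1e-12),
                          np.log(max(init.get("phi", 0.1 * dmax), 1e-6))))
    # jitter the default starts deterministically to dodge symmetric local optima
    starts += [
        (float(rng.uniform(0.1, 0.95)), float(np.log(dmax) + rng.uniform(-3.5, -0.5)))
    ]

    # correlation ranges beyond half the maximum pair distance are not
    # estimable from the data (the classical variogram half-lag rule) and
    # soak fixed-effect trends into the error process, so phi is capped
    bounds = [(1e-8, 1.0), (np.log(max(dmax, 1.0)) - 8.0, np.log(max(dmax / 2.0, 1.0)))]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            obj, x0=np.asarray(x0), method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitFailureError("restricted likelihood is non-finite at every start")

    alpha, log_phi = float(best.x[0]), float(best.x[1])
    nll = float(best.fun)
    # prefer independent errors when the likelihood cannot distinguish them
    nll_indep = _profiled_negloglik(1.0, log_phi, y, Xmat, dists, family)
    if nll_indep <= nll + 1e-8:
        alpha, nll = 1.0, float(nll_indep)

    phi = float(np.exp(log_phi))
    V = alpha * np.eye(n) + (1 - alpha) * _FAMILIES[family](dists, phi)
    L = linalg.cholesky(V, lower=True)
    Xi = linalg.solve_triangular(L, Xmat, lower=True)
    yi = linalg.solve_triangular(L, y, lower=True)
    XtX = Xi.T @ Xi
    beta = np.linalg.solve(XtX, Xi.T @ yi)
    r = yi - Xi @ beta
    s2 = float(r @ r) / (n - p)
    cov_beta = s2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov_beta))
    fitted = Xmat @ beta

    tau2, sigma2 = s2 * alpha, s2 * (1 - alpha)
    loglik = reml_loglik(y, Xmat, dists, tau2, sigma2, phi, family)
    return RegressionResult(
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        cov_params={"tau2": tau2, "sigma2": sigma2, "phi": phi},
        loglik=loglik,
        residuals=y - fitted,
        fitted=fitted,
        class_label=class_label,
        meta={"family": family, "estimation": "REML (profiled scale + coefficients)",
              "n": n, "seed": seed},
    )


def _decorrelated_residuals(result: RegressionResult, coords: np.ndarray) -> np.ndarray:
    n = len(result.residuals)
    cp = result.cov_params
    family = result.meta.get("family", "exponential")
    dists = squareform(pdist(np.asarray(coords, float)))
    Sigma = cp["tau2"] * np.eye(n) + cp["sigma2"] * _FAMILIES[family](dists, cp["phi"])
    L = linalg.cholesky(Sigma, lower=True)
    return linalg.solve_triangular(L, result.residuals, lower=True)


def diagnostics(result: RegressionResult, coords: np.ndarray) -> DiagnosticsReport:
    """Residual checks on the decorrelated (whitened) residuals:
    Shapiro-Wilk for normality and a Breusch-Pagan-type score test
    (squared residuals on fitted values) for heteroscedasticity."""
    if len(result.residuals) < 8:
        raise ValueError("diagnostics need at least 8 residuals")
    e = _decorrelated_residuals(result, coords)
    if np.ptp(e) == 0:
        raise ValueError("residuals are constant; diagnostics are undefined")
    w_stat, w_p = stats.shapiro(e)

    from statsmodels.stats.diagnostic import het_breuschpagan

    exog = np.column_stack([np.ones_like(result.fitted), result.fitted])
    if np.ptp(result.fitted) == 0:
        raise ValueError("fitted values are constant; heteroscedasticity test undefined")
    lm, lm_p, _, _ = het_breuschpagan(e, exog)
    return DiagnosticsReport(
        normality_stat=float(w_stat), normality_p=float(w_p),
        het_stat=float(lm), het_p=float(lm_p),
    )


def drop_and_refit(
    result: RegressionResult,
    y: np.ndarray,
    X: HabitatMatrix | pd.DataFrame,
    coords: np.ndarray,
    rule: str = "se",
    z_crit: float = 1.96,
) -> RegressionResult:
    """Remove non-significant covariates and refit the reduced design.

    With ``rule="se"`` a non-intercept term is removed when the interval
    beta +/- se contains zero (|beta| <= se); ``rule="z"`` uses
    |beta| <= z_crit * se instead.  The intercept is always retained.
    Returns the input result unchanged when nothing is removed.
    """
    crit = 1.0 if rule == "se" else float(z_crit)
    keep, removed = [], []
    for term in result.terms:
        if term == "const":
            continue
        (removed if abs(result.params[term]) <= crit * result.se[term] else keep).append(term)
    if not removed:
        return result
    df = X.data if isinstance(X, HabitatMatrix) else X
    if not keep:
        warnings.warn("all covariates removed; returning intercept-only fit")
    reduced = df[keep]
    refit = fit_gls(
        y, reduced, coords,
        seed=result.meta.get("seed", 0),
        family=result.meta.get("family", "exponential"),
        class_label=result.class_label,
    )
    refit.removed = removed
    refit.meta["reduced_from"] = result.terms
    refit.meta["removal_rule"] = f"|beta| <= {crit:g} * se"
    return refit


def effect_per_unit(
    result: RegressionResult, covariate: str, delta: float, matrix: HabitatMatrix
) -> float:
    """Predicted change in KDE percentile for a ``delta`` change of the
    covariate in natural units: beta_std * delta / column_sd."""
    if covariate not in result.params.index:
        raise ValueError(f"covariate {covariate!r} not in the fitted model")
    if matrix.column_sds is None or covariate not in matrix.column_sds.index:
        raise ValueError(f"covariate {covariate!r} has no stored scale")
    return float(result.params[covariate] * delta / matrix.column_sds[covariate])
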