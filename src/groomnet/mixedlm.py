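"""Gaussian linear mixed model with two crossed random intercepts.

Model: y = X b + Z1 u + Z2 v + e with u ~ N(0, s1^2 I), v ~ N(0, s2^2 I),
e ~ N(0, se^2 I), so V = se^2 I + s1^2 Z1 Z1' + s2^2 Z2 Z2'. The two
grouping factors here are individual identity and observation time period,
which cross rather than nest (the same individual appears in many periods).

Estimation maximizes the (restricted) log-likelihood over log-variances
with L-BFGS-B from two starting points; the sample sizes this package
meets (about a hundred rows, a few dozen random-effect levels) make the
direct dense-Cholesky evaluation of V cheap, so no sparse or profiled
tricks are used.

Satterthwaite denominator degrees of freedom for a 1-df contrast L follow
the standard recipe: with f(th) = L (X' V(th)^-1 X)^-1 L' evaluated at the
REML estimate and A the asymptotic covariance of the variance components
(twice the inverse Hessian of the REML deviance), df = 2 f^2 / (g' A g)
where g is the gradient of f. Derivatives are numerical (central
differences, forward at a variance boundary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

_LOG_BOUNDS = (-25.0, 12.0)


@dataclass
class CoreFit:
    """Raw fit state shared by the inference layer and the df machinery."""

    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray
    varcomps: np.ndarray  # (sigma2_id, sigma2_period, sigma2_resid)
    loglik: float
    reml: bool
    converged: bool
    n: int
    p: int
    y: np.ndarray
    X: np.ndarray
    Z1: np.ndarray
    Z2: np.ndarray


def _indicator(codes: np.ndarray) -> np.ndarray:
    codes = np.asarray(codes)
    _, inv = np.unique(codes, return_inverse=True)
    Z = np.zeros((len(codes), inv.max() + 1))
    Z[np.arange(len(codes)), inv] = 1.0
    return Z


def _profile(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
             G1: np.ndarray, G2: np.ndarray, reml: bool):
    """Return (-2 log lik, beta, cov_beta) at variance components theta."""
    n, p = X.shape
    V = theta[2] * np.eye(n) + theta[0] * G1 + theta[1] * G2
    try:
        c, low = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError:
        return np.inf, None, None
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    Vi_X = linalg.cho_solve((c, low), X)
    Vi_y = linalg.cho_solve((c, low), y)
    XtViX = X.T @ Vi_X
    try:
        with warnings.catch_warnings():
            # transient near-singular systems during optimizer excursions
            warnings.simplefilter("ignore", linalg.LinAlgWarning)
            beta = linalg.solve(XtViX, X.T @ Vi_y, assume_a="pos")
            cov_beta = linalg.inv(XtViX)
    except linalg.LinAlgError:
        return np.inf, None, None
    r = y - X @ beta
    quad = float(r @ linalg.cho_solve((c, low), r))
    if reml:
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf, None, None
        obj = (n - p) * np.log(2 * np.pi) + logdet_v + logdet_x + quad
    else:
        obj = n * np.log(2 * np.pi) + logdet_v + quad
    return obj, beta, cov_beta


def fit_core(y: np.ndarray, X: np.ndarray, id_codes: np.ndarray,
             period_codes: np.ndarray, reml: bool = False) -> CoreFit:
    """Fit the crossed-intercept LMM by (RE)ML over log-variances."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n != len(y):
        raise ValueError("y and X disagree on n")
    Z1 = _indicator(id_codes)
    Z2 = _indicator(period_codes)
    G1 = Z1 @ Z1.T
    G2 = Z2 @ Z2.T

    # OLS residual variance anchors the starting values.
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    s2 = float(resid @ resid) / max(n - p, 1)
    s2 = max(s2, 1e-10)
    starts = [
        np.log([0.2 * s2, 0.2 * s2, 0.8 * s2]),
        np.log([1e-6 * s2, 1e-6 * s2, s2]),
    ]

    def objective(log_theta: np.ndarray) -> float:
        obj, _, _ = _profile(np.exp(log_theta), y, X, G1, G2, reml)
        return obj if np.isfinite(obj) else 1e12

    best = None
    converged = False
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B",
            bounds=[_LOG_BOUNDS] * 3,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
            converged = bool(res.success)
        elif abs(res.fun - best.fun) <= 1e-10:
            converged = converged or bool(res.success)
    theta = np.exp(best.x)
    obj, beta, cov_beta = _profile(theta, y, X, G1, G2, reml)
    if beta is None:
        raise linalg.LinAlgError("singular covariance at the optimum")
    return CoreFit(
        beta=beta, se=np.sqrt(np.diag(cov_beta)), cov_beta=cov_beta,
        varcomps=theta, loglik=-0.5 * obj, reml=reml,
        converged=converged and np.isfinite(obj),
        n=n, p=p, y=y, X=X, Z1=Z1, Z2=Z2)


def _contrast_var(theta: np.ndarray, fit: CoreFit, L: np.ndarray) -> float:
    """f(theta) = L (X' V^-1 X)^-1 L' for a 1-row contrast."""
    n = fit.n
    V = (theta[2] * np.eye(n) + theta[0] * (fit.Z1 @ fit.Z1.T)
         + theta[1] * (fit.Z2 @ fit.Z2.T))
    c, low = linalg.cho_factor(V, lower=True)
    XtViX = fit.X.T @ linalg.cho_solve((c, low), fit.X)
    return float(L @ linalg.solve(XtViX, L, assume_a="pos"))


def _steps(theta: np.ndarray) -> np.ndarray:
    scale = max(float(np.max(theta)), 1e-8)
    return np.maximum(1e-7 * scale, 1e-4 * theta)


def _reml_hessian(fit: CoreFit) -> np.ndarray:
    """Numerical Hessian of the REML deviance w.r.t. the variances."""
    G1 = fit.Z1 @ fit.Z1.T
    G2 = fit.Z2 @ fit.Z2.T

    def dev(theta: np.ndarray) -> float:
        obj, _, _ = _profile(np.maximum(theta, 0.0), fit.y, fit.X, G1, G2,
                             reml=True)
        return obj

    theta = fit.varcomps
    h = _steps(theta)
    H = np.zeros((3, 3))
    f0 = dev(theta)
    for i in range(3):
        for j in range(i, 3):
            ei = np.zeros(3); ei[i] = h[i]
            ej = np.zeros(3); ej[j] = h[j]
            # shift the stencil inside the feasible orthant at a boundary
            base = theta.copy()
            for k, e in ((i, h[i]), (j, h[j])):
                if base[k] - e < 0:
                    base[k] = e
            if i == j:
                H[i, i] = (dev(base + ei) - 2 * dev(base)
                           + dev(base - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    dev(base + ei + ej) - dev(base + ei - ej)
                    - dev(base - ei + ej) + dev(base - ei - ej)
                ) / (4 * h[i] * h[j])
    del f0
    return H


def satterthwaite_df(fit: CoreFit, L: np.ndarray) -> float:
    """Satterthwaite denominator df for the 1-df contrast L.

    Returns NaN when the variance-component Hessian is not usable (the
    caller falls back to a residual-df rule).
    """
    if not fit.reml:
        raise ValueError("Satterthwaite df requires a REML fit")
    L = np.asarray(L, dtype=float).ravel()
    theta = fit.varcomps
    f_hat = _contrast_var(theta, fit, L)

    h = _steps(theta)
    grad = np.zeros(3)
    for i in range(3):
        hi = h[i]
        if theta[i] - hi >= 0:
            tp = theta.copy(); tp[i] += hi
            tm = theta.copy(); tm[i] -= hi
            grad[i] = (_contrast_var(tp, fit, L)
                       - _contrast_var(tm, fit, L)) / (2 * hi)
        else:
            tp = theta.copy(); tp[i] += hi
            grad[i] = (_contrast_var(tp, fit, L) - f_hat) / hi

    try:
        H = _reml_hessian(fit)
        A = 2.0 * linalg.inv(H)
    except linalg.LinAlgError:
        return float("nan")
    denom = float(grad @ A @ grad)
    if not np.isfinite(denom) or denom <= 0:
        return float("nan")
    df = 2.0 * f_hat ** 2 / denom
    if not np.isfinite(df) or df <= 0:
        return float("nan")
    return min(df, float(fit.n - fit.p))
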