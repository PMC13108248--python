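"""Random-intercept linear mixed models with Satterthwaite degrees of freedom.

The longitudinal models used throughout this package all share one
random-effects structure: a single random intercept per subject,

    y = X beta + Z b + e,   b_g ~ N(0, tau^2),   e ~ N(0, sigma^2 I).

Fitting is delegated to ``statsmodels`` MixedLM (REML).  statsmodels does
not provide Satterthwaite degrees of freedom, so they are computed here
directly: for this covariance structure every per-group marginal covariance
is ``V_g = sigma^2 I + tau^2 11'``, which has a closed-form inverse and
determinant (Sherman-Morrison), making the restricted log-likelihood cheap
to evaluate.  For a contrast ``c`` the Satterthwaite approximation is

    df = 2 f(theta)^2 / (g' A g),   f(theta) = c' (X' V(theta)^-1 X)^-1 c,

with ``g`` the gradient of ``f`` in the variance parameters and ``A`` the
asymptotic covariance of the REML variance estimates (inverse observed
information), both obtained by central finite differences on the
log-variance scale (the quadratic form is invariant to smooth
reparameterization at the optimum).  If the information matrix is not
positive definite — e.g. the random-intercept variance is on the zero
boundary — the per-effect df falls back to the residual df ``n - p`` and
the result is marked accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = ["RandomInterceptFit", "fit_random_intercept"]


@dataclass
class RandomInterceptFit:
    """Fixed-effect estimates with per-effect Satterthwaite df."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    df: np.ndarray
    p: np.ndarray
    sigma2: float
    tau2: float
    n_obs: int
    n_groups: int
    converged: bool
    df_method: str  # "satterthwaite" or "residual"


class _RIProfile:
    """Per-group sufficient statistics for the random-intercept REML surface."""

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        self.n, self.p = X.shape
        self.blocks = []
        for g in pd.unique(groups):
            sel = groups == g
            Xg, yg = X[sel], y[sel]
            self.blocks.append(
                (
                    len(yg),
                    Xg.T @ Xg,
                    Xg.T @ yg,
                    Xg.sum(axis=0),
                    yg.sum(),
                    yg @ yg,
                )
            )
        self.n_groups = len(self.blocks)

    def _assemble(self, sigma2: float, tau2: float):
        """X'V^-1 X, X'V^-1 y, and the log|V| / quadratic pieces."""
        p = self.p
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        logdet = 0.0
        yty = 0.0
        for ng, XtX, Xty, sx, sy, syy in self.blocks:
            w = tau2 / (sigma2 + ng * tau2)
            XtVX += XtX - w * np.outer(sx, sx)
            XtVy += Xty - w * sx * sy
            yty += syy - w * sy * sy
            logdet += ng * np.log(sigma2) + np.log1p(ng * tau2 / sigma2)
        return XtVX / sigma2, XtVy / sigma2, yty / sigma2, logdet

    def beta_cov(self, sigma2: float, tau2: float):
        XtVX, XtVy, _, _ = self._assemble(sigma2, tau2)
        C = np.linalg.inv(XtVX)
        return C @ XtVy, C

    def reml_loglike(self, sigma2: float, tau2: float) -> float:
        XtVX, XtVy, yty, logdet = self._assemble(sigma2, tau2)
        C = np.linalg.inv(XtVX)
        beta = C @ XtVy
        quad = yty - XtVy @ beta  # r' V^-1 r at the GLS solution
        sign, logdet_XtVX = np.linalg.slogdet(XtVX)
        return -0.5 * (logdet + logdet_XtVX + quad)

    def contrast_var(self, c: np.ndarray, sigma2: float, tau2: float) -> float:
        _, C = self.beta_cov(sigma2, tau2)
        return float(c @ C @ c)


def _fd_grad_hess(fun, eta: np.ndarray, rel_step: float = 1e-4):
    """Central-difference gradient and Hessian of a scalar function."""
    k = len(eta)
    h = rel_step * np.maximum(np.abs(eta), 1.0)
    grad = np.zeros(k)
    hess = np.zeros((k, k))
    f0 = fun(eta)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        fp, fm = fun(eta + ei), fun(eta - ei)
        grad[i] = (fp - fm) / (2 * h[i])
        hess[i, i] = (fp - 2 * f0 + fm) / h[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i], ej[j] = h[i], h[j]
            fpp = fun(eta + ei + ej)
            fpm = fun(eta + ei - ej)
            fmp = fun(eta - ei + ej)
            fmm = fun(eta - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return grad, hess


def fit_random_intercept(
    formula: str,
    data: pd.DataFrame,
    group_col: str,
) -> RandomInterceptFit:
    """Fit ``formula`` with a per-``group_col`` random intercept by REML.

    Non-convergence is flagged on the result rather than raised.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data[group_col])
        try:
            res = model.fit(reml=True, method=["lbfgs", "bfgs", "cg"])
            converged = bool(getattr(res, "converged", True))
        except Exception:
            res = model.fit(reml=True, method="powell", maxiter=500)
            converged = False

    y = np.asarray(model.endog, dtype=float)
    X = np.asarray(model.exog, dtype=float)
    groups = np.asarray(data[group_col])
    terms = list(model.exog_names)
    sigma2 = float(res.scale)
    tau2 = float(np.asarray(res.cov_re)[0, 0])
    prof = _RIProfile(y, X, groups)

    # refine on the closed-form REML surface (log scale); also guards against
    # any backend scaling-convention drift
    tau2 = max(tau2, 1e-10 * sigma2)
    from scipy.optimize import minimize

    opt = minimize(
        lambda eta: -prof.reml_loglike(np.exp(eta[0]), np.exp(eta[1])),
        np.log([sigma2, tau2]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 400},
    )
    sigma2, tau2 = np.exp(opt.x)

    beta, C = prof.beta_cov(sigma2, tau2)
    se = np.sqrt(np.diag(C))
    tvals = beta / se

    eta_hat = np.log([sigma2, tau2])
    _, hess_l = _fd_grad_hess(
        lambda e: prof.reml_loglike(np.exp(e[0]), np.exp(e[1])), eta_hat
    )
    dfs = np.empty(len(terms))
    df_method = "satterthwaite"
    resid_df = max(prof.n - prof.p, 1)
    try:
        A = np.linalg.inv(-hess_l)
        ok = np.all(np.linalg.eigvalsh(-hess_l) > 0)
    except np.linalg.LinAlgError:
        ok = False
    if not ok:
        dfs[:] = resid_df
        df_method = "residual"
    else:
        for j in range(len(terms)):
            c = np.zeros(len(terms))
            c[j] = 1.0
            f = prof.contrast_var(c, sigma2, tau2)
            g, _ = _fd_grad_hess(
                lambda e: prof.contrast_var(c, np.exp(e[0]), np.exp(e[1])), eta_hat
            )
            denom = float(g @ A @ g)
            if denom <= 0 or not np.isfinite(denom):
                dfs[j] = resid_df
                df_method = "residual"
            else:
                dfs[j] = min(2.0 * f * f / denom, resid_df * 10.0)
                if dfs[j] <= 0 or not np.isfinite(dfs[j]):
                    dfs[j] = resid_df
                    df_method = "residual"

    from scipy import stats as sps

    pvals = 2.0 * sps.t.sf(np.abs(tvals), dfs)
    return RandomInterceptFit(
        terms=terms,
        beta=beta,
        se=se,
        t=tvals,
        df=dfs,
        p=pvals,
        sigma2=float(sigma2),
        tau2=float(tau2),
        n_obs=prof.n,
        n_groups=prof.n_groups,
        converged=converged,
        df_method=df_method,
    )
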