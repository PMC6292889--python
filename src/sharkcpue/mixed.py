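"""Frequentist mixed models: REML linear and Laplace binomial GLMMs.

Both models use random intercepts for one or more grouping factors
(typically region and site-within-region).

* :func:`fit_lmm` — linear mixed model estimated by REML. The marginal
  covariance ``V = sigma^2 (I + sum_k gamma_k Z_k Z_k')`` is handled through
  the Woodbury identity (the random-effect dimension is small), the
  variance ratios ``gamma_k`` are optimized on the log scale, and
  ``sigma^2`` is profiled out in closed form.
* :func:`fit_binomial_glmm` — logistic mixed model via the Laplace
  approximation: penalized IRLS finds the joint mode of (beta, u), the
  log-marginal uses the u-block Hessian determinant, and the random-effect
  standard deviations are optimized in an outer loop.

Boundary fits (a variance ratio driven to ~0) are reported through the
``singular`` flag, never hidden; complete separation in the logistic model
is detected and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit
from scipy.stats import norm

from .errors import DataError

_SINGULAR_GAMMA = 1e-6


def significance_stars(p: float) -> str:
    """``***`` p<0.001, ``**`` p<0.01, ``*`` p<0.05, else ``ns``."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _indicator(codes: np.ndarray) -> np.ndarray:
    m = codes.max() + 1
    Z = np.zeros((codes.size, m))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


@dataclass
class LMMResult:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    sigma2: float
    variance_components: dict[str, float]
    reml_criterion: float
    n: int
    singular: bool
    p_values: np.ndarray = field(default=None)

    def summary(self) -> dict:
        out = {}
        for i, name in enumerate(self.names):
            out[name] = {
                "estimate": float(self.beta[i]),
                "se": float(self.se[i]),
                "p": float(self.p_values[i]),
                "stars": significance_stars(float(self.p_values[i])),
            }
        return out


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str],
    groups: dict[str, np.ndarray],
) -> LMMResult:
    """REML fit of a random-intercept linear mixed model.

    ``groups`` maps factor name -> integer codes (length n). With no
    groups the fit reduces exactly to ordinary least squares.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise DataError("more parameters than observations")
    Zs = {k: _indicator(np.asarray(c)) for k, c in groups.items()}
    keys = list(Zs)

    def profile(log_gamma: np.ndarray):
        gam = np.exp(log_gamma)
        if keys:
            Z = np.hstack([np.sqrt(g) * Zs[k] for k, g in zip(keys, gam)])
            C = Z.T @ Z
            C[np.diag_indices_from(C)] += 1.0
            cf = cho_factor(C, lower=True)
            logdet_vt = 2.0 * np.sum(np.log(np.diag(cf[0])))

            def vinv(a):
                return a - Z @ cho_solve(cf, Z.T @ a)
        else:
            logdet_vt = 0.0

            def vinv(a):
                return a

        WX = vinv(X)
        XtWX = X.T @ WX
        XtWy = WX.T @ y
        beta = np.linalg.solve(XtWX, XtWy)
        qf = float(y @ vinv(y) - beta @ XtWy)
        sigma2 = max(qf / (n - p), 1e-300)  # 0 only for perfect fits
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        crit = ((n - p) * np.log(sigma2) + logdet_vt + logdet_xwx
                + (n - p))
        return crit, beta, sigma2, XtWX

    if keys:
        x0 = np.zeros(len(keys))
        res = optimize.minimize(
            lambda lg: profile(np.clip(lg, -20, 20))[0], x0,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
        )
        log_gamma = np.clip(res.x, -20, 20)
    else:
        log_gamma = np.zeros(0)
    crit, beta, sigma2, XtWX = profile(log_gamma)
    gam = np.exp(log_gamma)
    cov_beta = sigma2 * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov_beta))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf)
    pvals = 2.0 * norm.sf(np.abs(z))
    return LMMResult(
        names=list(names), beta=beta, se=se, sigma2=float(sigma2),
        variance_components={k: float(sigma2 * g) for k, g in zip(keys, gam)},
        reml_criterion=float(crit), n=n,
        singular=bool(keys) and bool((gam < _SINGULAR_GAMMA).any()),
        p_values=pvals,
    )


@dataclass
class BinomialGLMMResult:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    variance_components: dict[str, float]
    log_marginal: float
    n: int
    singular: bool
    separation: bool
    p_values: np.ndarray = field(default=None)
    cov_beta: np.ndarray = field(default=None)


def fit_binomial_glmm(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str],
    groups: dict[str, np.ndarray],
    max_inner: int = 200,
) -> BinomialGLMMResult:
    """Laplace-approximate ML fit of a random-intercept logistic model.

    With no groups (or variances at the boundary) the estimates coincide
    with plain logistic maximum likelihood.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise DataError("response must be binary 0/1")
    if y.min() == y.max():
        raise DataError("both outcome classes must be present")
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    Zs = {k: _indicator(np.asarray(c)) for k, c in groups.items()}
    keys = list(Zs)
    sizes = [Zs[k].shape[1] for k in keys]
    q = int(sum(sizes))
    D = np.hstack([X] + [Zs[k] for k in keys]) if keys else X

    def joint_mode(log_sigma: np.ndarray, coef0=None):
        pen = np.zeros(p + q)
        off = p
        for sz, ls in zip(sizes, log_sigma):
            pen[off:off + sz] = np.exp(-2.0 * ls)
            off += sz
        coef = np.zeros(p + q) if coef0 is None else coef0.copy()
        for _ in range(max_inner):
            eta = D @ coef
            mu = expit(eta)
            w = mu * (1.0 - mu) + 1e-12
            grad = D.T @ (y - mu) - pen * coef
            H = (D.T * w) @ D
            H[np.diag_indices_from(H)] += pen + 1e-12
            step = np.linalg.solve(H, grad)
            coef = coef + step
            if np.max(np.abs(step)) < 1e-10:
                break
        return coef, H, pen

    def neg_log_marginal(log_sigma: np.ndarray):
        log_sigma = np.clip(log_sigma, -8, 8)
        coef, H, pen = joint_mode(log_sigma)
        eta = D @ coef
        ll = float(y @ eta - np.sum(np.logaddexp(0.0, eta)))
        upen = float(np.sum(pen[p:] * coef[p:] ** 2))
        H_uu = H[p:, p:]
        if q:
            sign, logdet_h = np.linalg.slogdet(H_uu)
            logdet_d = 2.0 * float(np.sum(
                np.array(sizes) * np.asarray(log_sigma)))
            lm = ll - 0.5 * upen - 0.5 * logdet_d - 0.5 * logdet_h
        else:
            lm = ll
        return -lm, coef, H

    if keys:
        res = optimize.minimize(
            lambda ls: neg_log_marginal(ls)[0], np.zeros(len(keys)),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 1000},
        )
        log_sigma = np.clip(res.x, -8, 8)
    else:
        log_sigma = np.zeros(0)
    nlm, coef, H = neg_log_marginal(log_sigma)
    cov = np.linalg.inv(H)
    beta = coef[:p]
    se = np.sqrt(np.diag(cov)[:p])
    separation = bool(np.max(np.abs(D @ coef)) > 30.0
                      or np.max(np.abs(beta)) > 25.0)
    z = beta / se
    pvals = 2.0 * norm.sf(np.abs(z))
    sig2 = {k: float(np.exp(2.0 * ls)) for k, ls in zip(keys, log_sigma)}
    return BinomialGLMMResult(
        names=list(names), beta=beta, se=se,
        variance_components=sig2, log_marginal=float(-nlm), n=n,
        singular=bool(keys) and any(v < _SINGULAR_GAMMA for v in sig2.values()),
        separation=separation, p_values=pvals, cov_beta=cov[:p, :p],
    )
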