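"""Maximum-likelihood spatial error model and its diagnostics.

Model: y = X beta + u,  u = lambda W u + eps,  eps ~ N(0, sigma^2 I),
with W a row-standardized contiguity matrix. Writing B(lambda) = I - lambda W,
the log-likelihood concentrated in lambda is

    beta(lambda)  = (X'B'BX)^{-1} X'B'B y
    sigma2(lambda)= e'e / n,          e = B (y - X beta(lambda))
    L(lambda)     = -(n/2)(ln 2pi + 1 + ln sigma2) + sum_i ln(1 - lambda w_i)

where w_i are the eigenvalues of W.  lambda is maximized by bounded scalar
optimization over the admissible interval (1/w_min, 1/w_max); for
row-standardized weights w_max = 1.  At lambda = 0 the model reduces exactly
to OLS with the Gaussian MLE variance e'e/n, which makes the likelihood-ratio
diagnostic for spatial dependence (1 df chi-square) well defined.

Standard errors come from the numerical Hessian of the full log-likelihood
in (beta, lambda, sigma^2) at the optimum; coefficient p-values are
asymptotic two-sided normal z-tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, stats

from .weights import SpatialWeights

__all__ = ["OLSFit", "SEMFit", "fit_ols", "fit_sem_ml", "lr_spatial_dependence"]

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-20  # guards ln(sigma2) for exact fits
_EIG_SHRINK = 1e-5  # keeps 1 - lambda*w away from 0 in the log-Jacobian


class ModelError(ValueError):
    """Raised for rank deficiency, degenerate eigen-intervals, etc."""


@dataclass(frozen=True)
class OLSFit:
    names: tuple[str, ...]
    beta: np.ndarray
    se_beta: np.ndarray
    sigma2: float  # MLE, e'e/n
    loglik: float
    resid: np.ndarray
    n: int
    k: int


@dataclass(frozen=True)
class SEMFit:
    """Spatial error model estimate in the layout of a regression table."""

    names: tuple[str, ...]
    beta: np.ndarray
    se_beta: np.ndarray
    z_beta: np.ndarray
    p_beta: np.ndarray
    lam: float
    se_lam: float
    sigma2: float
    loglik_sem: float
    loglik_ols: float
    lr_stat: float
    lr_p: float
    r_squared: float
    n: int
    k: int
    lam_bounds: tuple[float, float]

    def summary_frame(self):
        import pandas as pd

        rows = pd.DataFrame(
            {
                "term": list(self.names),
                "coeff": self.beta,
                "se": self.se_beta,
                "z": self.z_beta,
                "p": self.p_beta,
            }
        )
        extra = pd.DataFrame(
            {
                "term": ["lambda", "lr_spatial_dependence_p", "r_squared"],
                "coeff": [self.lam, np.nan, np.nan],
                "se": [self.se_lam, np.nan, np.nan],
                "z": [np.nan, np.nan, np.nan],
                "p": [np.nan, self.lr_p, self.r_squared],
            }
        )
        return pd.concat([rows, extra], ignore_index=True)


def _design(y, X, names):
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if y.shape[0] != n:
        raise ModelError(f"y has {y.shape[0]} rows, X has {n}")
    if n <= k:
        raise ModelError(f"need n > k (n={n}, k={k})")
    if np.linalg.matrix_rank(X) < k:
        raise ModelError("X is rank deficient")
    if names is None:
        names = tuple(f"x{j}" for j in range(k))
    if len(names) != k:
        raise ModelError("names length must match number of columns")
    return y, X, tuple(names), n, k


def _gauss_loglik(n: int, sigma2: float) -> float:
    return -0.5 * n * (np.log(2 * np.pi) + 1.0 + np.log(max(sigma2, _VAR_FLOOR)))


def fit_ols(y, X, names: tuple[str, ...] | None = None) -> OLSFit:
    """Ordinary least squares with the Gaussian MLE log-likelihood.

    The reported ``sigma2`` is the MLE e'e/n (so the log-likelihood is the
    lambda = 0 value of the SEM concentrated likelihood); coefficient
    standard errors use the conventional unbiased e'e/(n-k) variance.
    """
    y, X, names, n, k = _design(y, X, names)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2_ml = rss / n
    s2_unbiased = rss / (n - k)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(xtx_inv) * s2_unbiased, 0.0, None))
    return OLSFit(
        names=names,
        beta=beta,
        se_beta=se,
        sigma2=sigma2_ml,
        loglik=_gauss_loglik(n, sigma2_ml),
        resid=resid,
        n=n,
        k=k,
    )


def _weights_eigenvalues(w: SpatialWeights) -> np.ndarray:
    """Eigenvalues of the row-standardized W.

    W = D^{-1} A with A symmetric is similar to the symmetric matrix
    D^{-1/2} A D^{-1/2}, so its spectrum is real and is computed with a
    symmetric solver for stability.
    """
    A = w.binary_adjacency().toarray()
    d = A.sum(axis=1)
    if (d == 0).any():
        raise ModelError(
            "weights contain islands; drop them before fitting "
            f"(islands: {w.islands})"
        )
    dis = 1.0 / np.sqrt(d)
    M = A * dis[:, None] * dis[None, :]
    return linalg.eigvalsh(M)


def fit_sem_ml(
    y,
    X,
    w: SpatialWeights,
    names: tuple[str, ...] | None = None,
    lam_fixed: float | None = None,
) -> SEMFit:
    """Fit the spatial error model by concentrated maximum likelihood.

    ``lam_fixed`` pins the spatial parameter instead of estimating it
    (``lam_fixed=0`` reduces the model to OLS exactly).
    """
    y, X, names, n, k = _design(y, X, names)
    if w.n != n:
        raise ModelError(f"weights have {w.n} units, data have {n}")
    if w.islands:
        raise ModelError(f"weights contain islands: {w.islands}")

    omega = _weights_eigenvalues(w)
    w_min, w_max = float(omega.min()), float(omega.max())
    if w_min >= 0 or w_max <= 0:
        raise ModelError(
            f"degenerate eigenvalue range [{w_min:.4g}, {w_max:.4g}]; "
            "lambda interval is empty"
        )
    lam_lo = 1.0 / w_min + _EIG_SHRINK
    lam_hi = 1.0 / w_max - _EIG_SHRINK

    W = w.row_standardized().sparse()

    def profile(lam: float) -> tuple[float, np.ndarray, float]:
        By = y - lam * (W @ y)
        BX = X - lam * (W @ X)
        beta, *_ = np.linalg.lstsq(BX, By, rcond=None)
        e = By - BX @ beta
        sigma2 = max(float(e @ e) / n, _VAR_FLOOR)
        ll = _gauss_loglik(n, sigma2) + float(np.log1p(-lam * omega).sum())
        return ll, beta, sigma2

    if lam_fixed is not None:
        if not (lam_lo <= lam_fixed <= lam_hi):
            raise ModelError(
                f"lam_fixed={lam_fixed} outside ({lam_lo:.4g}, {lam_hi:.4g})"
            )
        lam_hat = float(lam_fixed)
        ll_sem, beta_hat, sigma2_hat = profile(lam_hat)
        ols = fit_ols(y, X, names)
        ll_ols = ols.loglik
    else:
        res = optimize.minimize_scalar(
            lambda lam: -profile(lam)[0],
            bounds=(lam_lo, lam_hi),
            method="bounded",
            options={"xatol": 1e-9},
        )
        if not np.isfinite(res.fun):
            raise ModelError("non-finite concentrated likelihood at the optimum")
        lam_hat = float(res.x)
        ll_sem, beta_hat, sigma2_hat = profile(lam_hat)

        ols = fit_ols(y, X, names)
        ll_ols = ols.loglik
        if ll_sem < ll_ols:  # interior optimum can only dominate lambda = 0
            lam_hat, ll_sem = 0.0, ll_ols
            _, beta_hat, sigma2_hat = profile(0.0)
    lr_stat = max(0.0, 2.0 * (ll_sem - ll_ols))
    lr_p = float(stats.chi2.sf(lr_stat, df=1))

    se_beta, se_lam = _sem_standard_errors(
        y, X, W, omega, beta_hat, lam_hat, sigma2_hat, (lam_lo, lam_hi)
    )
    z_beta = np.divide(
        beta_hat, se_beta, out=np.full(k, np.nan), where=se_beta > 0
    )
    p_beta = 2.0 * stats.norm.sf(np.abs(z_beta))

    resid_naive = y - X @ beta_hat
    var_y = float(np.var(y))
    r2 = 1.0 - float(np.var(resid_naive)) / var_y if var_y > 0 else np.nan

    return SEMFit(
        names=names,
        beta=beta_hat,
        se_beta=se_beta,
        z_beta=z_beta,
        p_beta=p_beta,
        lam=lam_hat,
        se_lam=se_lam,
        sigma2=sigma2_hat,
        loglik_sem=ll_sem,
        loglik_ols=ll_ols,
        lr_stat=lr_stat,
        lr_p=lr_p,
        r_squared=r2,
        n=n,
        k=k,
        lam_bounds=(lam_lo, lam_hi),
    )


def _sem_standard_errors(y, X, W, omega, beta, lam, sigma2, lam_bounds):
    """SEs from the numerical Hessian of the full log-likelihood."""
    n, k = X.shape

    def negll(theta):
        b = theta[:k]
        l_ = theta[k]
        s2 = theta[k + 1]
        if s2 <= 0 or not (lam_bounds[0] < l_ < lam_bounds[1]):
            return np.inf
        u = y - X @ b
        e = u - l_ * (W @ u)
        jac = float(np.log1p(-l_ * omega).sum())
        return 0.5 * n * np.log(2 * np.pi * s2) - jac + float(e @ e) / (2 * s2)

    theta = np.concatenate([beta, [lam, sigma2]])
    H = _numerical_hessian(negll, theta)
    if not np.all(np.isfinite(H)):
        logger.warning(
            "non-finite Hessian (near-singular fit, sigma2=%.3g); SEs set to NaN",
            sigma2,
        )
        return np.full(k, np.nan), float("nan")
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov).copy()
    except np.linalg.LinAlgError:
        diag = np.full(k + 2, np.nan)
    if np.any(diag[: k + 1] <= 0) or not np.all(np.isfinite(diag[: k + 1])):
        logger.warning("Hessian not positive definite; falling back to pinv")
        cov = np.linalg.pinv(H)
        diag = np.abs(np.diag(cov))
    se = np.sqrt(np.clip(diag, 0.0, None))
    return se[:k], float(se[k])


def _numerical_hessian(f, x, rel_step=1e-4):
    """Central-difference Hessian; step scaled to parameter magnitude."""
    m = len(x)
    h = rel_step * np.maximum(np.abs(x), 1e-3)
    H = np.empty((m, m))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(m):
            for j in range(i, m):
                ei = np.zeros(m)
                ej = np.zeros(m)
                ei[i] = h[i]
                ej[j] = h[j]
                fpp = f(x + ei + ej)
                fpm = f(x + ei - ej)
                fmp = f(x - ei + ej)
                fmm = f(x - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def lr_spatial_dependence(fit: SEMFit) -> tuple[float, float]:
    """Likelihood-ratio diagnostic for spatial error dependence (1 df)."""
    stat = max(0.0, 2.0 * (fit.loglik_sem - fit.loglik_ols))
    return stat, float(stats.chi2.sf(stat, df=1))
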