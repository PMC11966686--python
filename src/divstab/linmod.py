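"""Ordinary least squares with the pieces a piecewise SEM engine needs.

Each local submodel of a piecewise structural equation model is a Gaussian
linear regression.  Beyond coefficients we need, per submodel: standard
errors and two-sided t-tests for d-separation claims, the *maximum
likelihood* residual variance (RSS/n, not RSS/(n-p)) so that nested
log-likelihood differences are chi-square distributed, raw residuals for
correlated-error terms, and an exact free-parameter count for AICc.
statsmodels exposes all of this too, but a dedicated helper keeps the
simulation loops (hundreds of replicates x a dozen regressions each) cheap
and the parameter accounting explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import CollinearityError

__all__ = ["OlsFit", "fit_ols"]

# Residual variances below this (relative to the response variance) are
# treated as exact linear identities, e.g. log S_com = log phi + log S_pop
# computed from the same decomposition.
_EXACT_FIT_RTOL = 1e-12


@dataclass
class OlsFit:
    """A fitted Gaussian linear regression ``y ~ 1 + X``."""

    response: str
    predictors: list[str]
    coef: np.ndarray          # slopes, aligned with `predictors`
    intercept: float
    se: np.ndarray            # standard errors of the slopes (unbiased sigma^2)
    t_values: np.ndarray
    p_values: np.ndarray      # two-sided, t distribution on n - p df
    residuals: np.ndarray
    sigma2_ml: float          # RSS / n  (maximum-likelihood estimate)
    loglik: float             # Gaussian log-likelihood at the ML variance
    r_squared: float
    n: int
    n_params: int             # slopes + intercept + residual variance
    exact_fit: bool = field(default=False)

    def standardized(self, y_sd: float, x_sds: np.ndarray) -> np.ndarray:
        """Post-hoc standardized slopes: raw * SD(x) / SD(y)."""
        return self.coef * np.asarray(x_sds) / y_sd


def fit_ols(y: np.ndarray, X: np.ndarray, response: str = "y",
            predictors: list[str] | None = None) -> OlsFit:
    """Fit ``y ~ 1 + X`` by least squares.

    Parameters
    ----------
    y : (n,) response vector.
    X : (n, k) predictor matrix, *without* an intercept column; k may be 0.
    response, predictors : names carried through to the fit for reporting.

    Raises
    ------
    CollinearityError
        If the design matrix (with intercept) is rank deficient; the error
        names the aliased predictor columns.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape[0], X.shape[1]
    if predictors is None:
        predictors = [f"x{i}" for i in range(k)]
    design = np.column_stack([np.ones(n), X])
    p = k + 1

    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    tol = max(n, p) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    if np.any(diag < tol):
        aliased = [predictors[i - 1] for i in np.flatnonzero(diag < tol) if i > 0]
        raise CollinearityError(aliased or list(predictors))

    beta = np.linalg.solve(r, q.T @ y)
    fitted = design @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))

    sigma2_ml = rss / n
    exact = tss > 0 and rss <= _EXACT_FIT_RTOL * tss
    # Guard log(0): an exact identity still needs a finite log-likelihood.
    sigma2_safe = max(sigma2_ml, np.finfo(float).tiny)
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2_safe) + 1.0)

    dof = n - p
    if dof > 0 and rss > 0 and not exact:
        sigma2_unbiased = rss / dof
        rinv = np.linalg.inv(r)
        cov = sigma2_unbiased * (rinv @ rinv.T)
        se_all = np.sqrt(np.diag(cov))
        tvals = np.divide(beta, se_all, out=np.zeros_like(beta), where=se_all > 0)
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    else:
        # Saturated or exact fit: slopes are determined, no sampling variance.
        se_all = np.zeros(p)
        tvals = np.where(np.abs(beta) > 1e-8, np.inf, 0.0)
        pvals = np.where(np.abs(beta) > 1e-8, 0.0, 1.0)

    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return OlsFit(
        response=response,
        predictors=list(predictors),
        coef=beta[1:],
        intercept=float(beta[0]),
        se=se_all[1:],
        t_values=tvals[1:],
        p_values=pvals[1:],
        residuals=resid,
        sigma2_ml=sigma2_ml,
        loglik=float(loglik),
        r_squared=float(r2),
        n=n,
        n_params=p + 1,
        exact_fit=bool(exact),
    )
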