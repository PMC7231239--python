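"""Small vectorised GLM kernels used in resampling loops.

These exist because permutation and bootstrap inference refit the same
logistic model tens of thousands of times; a plain-numpy Newton solver and a
batched Rao score test keep those loops tractable.  Single user-facing fits
elsewhere in the package go through statsmodels; equality of the two routes
is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


class ConvergenceError(RuntimeError):
    """Raised when a likelihood fit fails to converge (e.g. separation)."""


def logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-10,
    beta0: np.ndarray | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Maximum-likelihood logistic regression via Newton-Raphson.

    Returns ``(beta, loglik, cov)`` where ``cov`` is the inverse observed
    information (Wald covariance).  Raises :class:`ConvergenceError` on
    non-convergence or quasi-separation (diverging coefficients).
    ``beta0`` warm-starts the iteration.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if beta0 is not None:
        beta = np.array(beta0, dtype=float)
    else:
        beta = np.zeros(k)
        # intercept warm start if a constant column is present
        ybar = min(max(y.mean(), 1e-9), 1 - 1e-9)
        const = np.where(np.all(X == X[0], axis=0) & (X[0] != 0))[0]
        if const.size:
            beta[const[0]] = np.log(ybar / (1 - ybar)) / X[0, const[0]]
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:  # singular information
            raise ConvergenceError("singular information matrix") from exc
        # dampen overly large steps (guards against separation blow-up)
        if np.max(np.abs(step)) > 10:
            step *= 10 / np.max(np.abs(step))
        beta = beta + step
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        if np.max(np.abs(beta)) > 40:
            raise ConvergenceError("coefficients diverging; possible separation")
        if abs(ll - ll_old) < tol and np.max(np.abs(grad)) < 1e-6:
            break
        ll_old = ll
    else:
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        if np.max(np.abs(X.T @ (y - p))) > 1e-4:
            raise ConvergenceError("IRLS did not converge")
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    w = p * (1.0 - p)
    H = (X * w[:, None]).T @ X
    cov = np.linalg.inv(H)
    return beta, ll, cov


def logistic_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def rao_score_test(
    X0: np.ndarray,
    y: np.ndarray,
    S: np.ndarray,
    null_beta: np.ndarray | None = None,
) -> np.ndarray:
    """Batched Rao score test p-values for adding each column of ``S``.

    ``X0`` is the null design (covariates incl. intercept), ``S`` an
    ``n x T`` matrix of candidate predictors tested one at a time.  The
    statistic is U^2/V with U = s'(y-p0) and V the efficient information of
    the added term given the null fit; asymptotically chi-square(1).
    """
    if null_beta is None:
        null_beta, _, _ = logistic_irls(X0, y)
    p0 = 1.0 / (1.0 + np.exp(-(X0 @ null_beta)))
    w = p0 * (1.0 - p0)
    U = S.T @ (y - p0)  # (T,)
    WX = X0 * w[:, None]
    XtWX_inv = np.linalg.inv(X0.T @ WX)
    StWX = S.T @ WX  # (T, k)
    V = np.einsum("ij,ij->j", S * w[:, None], S) - np.einsum(
        "tk,kl,tl->t", StWX, XtWX_inv, StWX
    )
    V = np.maximum(V, 1e-300)
    stat = U * U / V
    return stats.chi2.sf(stat, df=1)


def linear_partial_f_test(X0: np.ndarray, y: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Batched partial F-test p-values for adding each column of ``S`` to
    the linear model ``y ~ X0`` (equivalent to the t-test on the new term)."""
    n, k = X0.shape
    Q, _ = np.linalg.qr(X0)
    ry = y - Q @ (Q.T @ y)
    RS = S - Q @ (Q.T @ S)
    ss_y = ry @ ry
    num = RS.T @ ry
    den = np.einsum("ij,ij->j", RS, RS)
    r2 = np.zeros(S.shape[1])
    ok = den > 1e-12 * max(ss_y, 1.0)
    r2[ok] = (num[ok] ** 2) / (den[ok] * ss_y)
    r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
    df2 = n - k - 1
    F = r2 / (1.0 - r2) * df2
    return stats.f.sf(F, 1, df2)
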