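"""Random-intercept logistic regression for repeated binary outcomes.

Tests whether the score-outcome association differs across the assessment
ages (14/16/18): logit P(y_it = 1) = x_it' beta + b_i with b_i ~ N(0, s2),
fixed effects comprising the score (at Pt = 1), centred age, their
interaction, sex and four ancestry PCs.  The marginal likelihood integrates
the random intercept out per person with adaptive Gauss-Hermite quadrature
(integrand re-centred at each person's posterior mode and rescaled by its
curvature), and is maximized quasi-Newton over (beta, log sigma).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

from ._glm import ConvergenceError, logistic_irls


def _group_starts(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sort rows by person; return (order, start offsets, inverse index)."""
    order = np.argsort(groups, kind="mergesort")
    g = groups[order]
    starts = np.r_[0, 1 + np.flatnonzero(g[1:] != g[:-1])]
    person_of_row = np.repeat(np.arange(starts.size), np.diff(np.r_[starts, g.size]))
    return order, starts, person_of_row


def marginal_loglik(
    beta: np.ndarray,
    sigma: float,
    X: np.ndarray,
    y: np.ndarray,
    starts: np.ndarray,
    person_of_row: np.ndarray,
    n_nodes: int = 11,
    return_modes: bool = False,
):
    """Adaptive Gauss-Hermite marginal log-likelihood.

    Rows must already be grouped contiguously by person (see
    :func:`_group_starts`).  ``sigma`` may be arbitrarily small; the
    integrand then collapses onto b = 0 and the result approaches the plain
    logistic log-likelihood.
    """
    eta = X @ beta
    G = starts.size
    sig2 = sigma * sigma
    # posterior mode of b_i by damped Newton (concave in b)
    b = np.zeros(G)
    for _ in range(50):
        z = eta + b[person_of_row]
        p = special.expit(z)
        grad = np.add.reduceat(y - p, starts) - b / sig2
        curv = np.add.reduceat(p * (1 - p), starts) + 1.0 / sig2
        step = grad / curv
        b += step
        if np.max(np.abs(step)) < 1e-10:
            break
    tau = 1.0 / np.sqrt(curv)  # Laplace scale at the mode
    xk, wk = hermgauss(n_nodes)
    # nodes and total quadrature weight in log domain
    B = b[:, None] + np.sqrt(2.0) * tau[:, None] * xk[None, :]
    z = eta[:, None] + B[person_of_row]
    cond = np.add.reduceat(y[:, None] * z - np.logaddexp(0.0, z), starts, axis=0)
    log_prior = -0.5 * np.log(2 * np.pi * sig2) - B * B / (2 * sig2)
    log_w = np.log(np.sqrt(2.0) * tau)[:, None] + np.log(wk)[None, :] + xk[None, :] ** 2
    ll_i = special.logsumexp(cond + log_prior + log_w, axis=1)
    total = float(np.sum(ll_i))
    if return_modes:
        return total, b, tau
    return total


@dataclass
class GlmmResult:
    params: pd.DataFrame        # coef, se, z, p per fixed effect
    sigma2: float
    loglik: float
    interaction_term: str
    interaction_p: float
    n_persons: int
    n_obs: int
    n_nodes: int


class RandomInterceptLogit(BaseEstimator):
    """Logistic mixed model with one random intercept per person.

    ``fit(X, y, groups)`` expects a fixed-effects design matrix *without*
    an intercept column (one is added), binary responses and a person id
    per row.  Fitted attributes: ``coef_`` (with intercept first),
    ``sigma2_``, ``loglik_``, ``params_`` (coef/se/z/p table).
    Non-convergence triggers documented retries with more quadrature nodes
    and a rescaled optimizer start before raising.
    """

    def __init__(self, n_nodes: int = 11, max_retries: int = 2,
                 sigma_bounds: tuple[float, float] = (-6.0, 3.0)):
        self.n_nodes = n_nodes
        self.max_retries = max_retries
        self.sigma_bounds = sigma_bounds

    def fit(self, X, y, groups, feature_names: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        if np.unique(groups).size == len(groups):
            # no repeated measures: still legal, sigma is unidentified at 0
            pass
        order, starts, person_of_row = _group_starts(groups)
        Xs = np.column_stack([np.ones(len(y)), X])[order]
        ys = y[order]
        names = ["const"] + (
            feature_names
            if feature_names is not None
            else [f"x{i + 1}" for i in range(X.shape[1])]
        )

        beta0, _, _ = logistic_irls(Xs, ys)
        k = Xs.shape[1]

        def nll(theta: np.ndarray) -> float:
            return -marginal_loglik(
                theta[:k], np.exp(theta[k]), Xs, ys, starts, person_of_row,
                self._nodes,
            )

        lo, hi = self.sigma_bounds
        bounds = [(None, None)] * k + [(lo, hi)]
        self._nodes = self.n_nodes
        theta0 = np.r_[beta0, np.log(0.5)]
        res = None
        for attempt in range(self.max_retries + 1):
            res = optimize.minimize(
                nll, theta0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
            )
            if res.success or res.fun < np.inf:
                break
            self._nodes = 2 * self._nodes + 3  # escalate quadrature
            theta0 = np.r_[beta0 * 0.5, np.log(0.25)]  # rescaled restart
        if res is None or not np.isfinite(res.fun):
            raise ConvergenceError(f"GLMM failed to converge: {res}")
        theta = res.x
        self.coef_ = theta[:k]
        self.sigma2_ = float(np.exp(2 * theta[k]))
        self.loglik_ = -float(res.fun)

        H = _numerical_hessian(nll, theta)
        se = self._wald_se(H, theta, k, lo)
        z = self.coef_ / se
        pvals = 2 * stats.norm.sf(np.abs(z))
        self.params_ = pd.DataFrame(
            {"coef": self.coef_, "se": se, "z": z, "p": pvals}, index=names
        )
        self.feature_names_ = names
        self.n_persons_ = starts.size
        self.n_obs_ = len(ys)
        return self

    @staticmethod
    def _wald_se(H: np.ndarray, theta: np.ndarray, k: int, lo: float) -> np.ndarray:
        """SEs from the observed information; if log sigma sits on its lower
        bound (sigma ~ 0) that direction is flat, so invert the beta block."""
        at_boundary = theta[k] <= lo + 1e-6
        try:
            if at_boundary:
                raise np.linalg.LinAlgError
            cov = np.linalg.inv(H)
            var = np.diag(cov)[:k]
            if np.any(var <= 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            cov = np.linalg.inv(H[:k, :k])
            var = np.diag(cov)
        return np.sqrt(var)


def _numerical_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian (symmetric)."""
    k = x.size
    H = np.zeros((k, k))
    h = eps * np.maximum(1.0, np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def build_long_table(
    cohort: pd.DataFrame,
    std_score: np.ndarray,
    behaviour: str,
    ages: tuple[int, ...] = (14, 16, 18),
    covariates: tuple[str, ...] = ("sex", "pc1", "pc2", "pc3", "pc4"),
) -> pd.DataFrame:
    """Stack per-age binary columns (e.g. fasting14/16/18) into long format.

    The score is constant within person (calculated once at Pt = 1)."""
    frames = []
    for age in ages:
        col = f"{behaviour}{age}"
        if col not in cohort.columns:
            continue
        sub = cohort[["sample_id", *covariates]].copy()
        sub["age"] = age
        sub["y"] = cohort[col].to_numpy(dtype=float)
        sub["std_score"] = np.asarray(std_score, dtype=float)
        frames.append(sub)
    long = pd.concat(frames, ignore_index=True)
    return long.dropna(subset=["y", "std_score", *covariates]).reset_index(drop=True)


def fit_glmm_interaction(
    long_table: pd.DataFrame,
    n_nodes: int = 11,
    age_reference: float = 14.0,
    age_unit: float = 2.0,
) -> GlmmResult:
    """Fit the score-by-age random-intercept model on a long table.

    Age enters linearly, centred at ``age_reference`` and scaled by
    ``age_unit`` years (14/16/18 -> 0/1/2) for conditioning; coefficients
    for age terms are reported per year by rescaling back.
    """
    ages = np.sort(long_table["age"].unique())
    if ages.size < 2:
        raise ValueError("need at least two ages for the interaction model")
    t = long_table
    age_c = (t["age"].to_numpy(dtype=float) - age_reference) / age_unit
    s = t["std_score"].to_numpy(dtype=float)
    covs = [c for c in ("sex", "pc1", "pc2", "pc3", "pc4") if c in t.columns]
    X = np.column_stack([s, age_c, s * age_c] + [t[c].to_numpy(float) for c in covs])
    names = ["std_score", "age_c", "score_x_age"] + covs
    est = RandomInterceptLogit(n_nodes=n_nodes)
    est.fit(X, t["y"].to_numpy(dtype=float), t["sample_id"].to_numpy(),
            feature_names=names)
    params = est.params_.copy()
    # report age-scaled terms per year
    for term in ("age_c", "score_x_age"):
        params.loc[term, ["coef", "se"]] = params.loc[term, ["coef", "se"]] / age_unit
    return GlmmResult(
        params=params,
        sigma2=est.sigma2_,
        loglik=est.loglik_,
        interaction_term="score_x_age",
        interaction_p=float(params.loc["score_x_age", "p"]),
        n_persons=est.n_persons_,
        n_obs=est.n_obs_,
        n_nodes=n_nodes,
    )
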