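"""Counterfactual causal mediation: total effect, ADE and ACME.

Estimates how much of the score's effect on a disordered-eating outcome
runs through childhood zBMI, using the natural direct / indirect effect
simulation estimator: fit a linear mediator model M ~ T + X and an outcome
model Y ~ T + M + X (logistic for binary outcomes), then for every observed
covariate profile draw potential mediators M(t0), M(t1) from the mediator
model (including residual noise) and average the model-implied outcome
differences over profiles:

    ACME(t) = mean_i[ Y_i(t, M_i(t1)) - Y_i(t, M_i(t0)) ]
    ADE(t)  = mean_i[ Y_i(t1, M_i(t)) - Y_i(t0, M_i(t)) ]

Reported effects average over t in {t0, t1}; total = ACME + ADE holds
exactly by construction.  Binary-outcome effects are risk differences on
the probability scale; continuous ones are mean differences.  Inference is
a nonparametric bootstrap (both models refit per resample) or quasi-Bayesian
parameter draws; identification assumes sequential ignorability (no
unmeasured treatment-outcome, treatment-mediator or mediator-outcome
confounding given the covariates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from ._glm import ConvergenceError, logistic_irls

DEFAULT_COVARIATES = ["sex", "pc1", "pc2", "pc3", "pc4"]


class InferenceError(RuntimeError):
    """Too many resample refits failed to converge."""


@dataclass
class MediationResult:
    outcome: str
    family: str
    total: float
    ade: float
    acme: float
    total_ci: tuple[float, float]
    ade_ci: tuple[float, float]
    acme_ci: tuple[float, float]
    total_p: float
    ade_p: float
    acme_p: float
    proportion_mediated: float | None
    n: int
    n_resamples: int
    inference: str


def _fit_models(T, M, y, X, family):
    """Mediator OLS and outcome GLM; returns parameter tuples."""
    n = len(y)
    Dm = np.column_stack([np.ones(n), T, X])
    coef_m, *_ = np.linalg.lstsq(Dm, M, rcond=None)
    resid = M - Dm @ coef_m
    sigma_m = float(np.sqrt(resid @ resid / (n - Dm.shape[1])))
    Dy = np.column_stack([np.ones(n), T, M, X])
    if family == "logistic":
        coef_y, _, cov_y = logistic_irls(Dy, y)
    else:
        coef_y, *_ = np.linalg.lstsq(Dy, y, rcond=None)
        cov_y = None
    return coef_m, sigma_m, coef_y, cov_y, Dm, Dy


def _effects(coef_m, sigma_m, coef_y, X, family, rng, t0, t1, n_draws=1):
    """Simulate potential mediators and average the four potential outcomes."""
    n = X.shape[0]
    gamma_m = coef_m[2:]
    base_m = coef_m[0] + X @ gamma_m
    a = coef_m[1]
    alpha_y, cp, b = coef_y[0], coef_y[1], coef_y[2]
    base_y = alpha_y + X @ coef_y[3:]

    acme = ade = total = 0.0
    for _ in range(n_draws):
        eps = rng.standard_normal(n) * sigma_m
        M0 = base_m + a * t0 + eps
        M1 = base_m + a * t1 + eps

        def yhat(t, M):
            eta = base_y + cp * t + b * M
            return expit(eta) if family == "logistic" else eta

        y00 = yhat(t0, M0).mean()
        y01 = yhat(t0, M1).mean()
        y10 = yhat(t1, M0).mean()
        y11 = yhat(t1, M1).mean()
        acme += 0.5 * ((y01 - y00) + (y11 - y10))
        ade += 0.5 * ((y10 - y00) + (y11 - y01))
        total += y11 - y00
    return acme / n_draws, ade / n_draws, total / n_draws


def _resample_p(draws: np.ndarray) -> float:
    """Two-sided resampling p-value from the bootstrap distribution."""
    B = draws.size
    lo = np.sum(draws <= 0) + 1
    hi = np.sum(draws >= 0) + 1
    return float(min(1.0, 2.0 * min(lo, hi) / (B + 1)))


class CausalMediation:
    """Natural direct/indirect effect estimator, sklearn-style.

    Parameters mirror the analysis: ``treatment`` is the standardized score
    contrasted at the fixed levels ``t0=0`` and ``t1=1`` (a 1-SD shift; the
    cohort itself is never dichotomized), ``mediator`` the childhood zBMI
    column, ``covariates`` sex + four PCs.  ``fit(df)`` sets ``total_``,
    ``ade_``, ``acme_``, their percentile CIs and resampling p-values.
    """

    def __init__(
        self,
        outcome: str,
        mediator: str = "zbmi11",
        treatment: str = "std_score",
        covariates: list[str] | None = None,
        family: str = "auto",
        n_resamples: int = 1000,
        inference: str = "bootstrap",
        n_point_draws: int = 100,
        t0: float = 0.0,
        t1: float = 1.0,
        max_fail_fraction: float = 0.05,
        seed: int = 0,
    ):
        self.outcome = outcome
        self.mediator = mediator
        self.treatment = treatment
        self.covariates = covariates
        self.family = family
        self.n_resamples = n_resamples
        self.inference = inference
        self.n_point_draws = n_point_draws
        self.t0 = t0
        self.t1 = t1
        self.max_fail_fraction = max_fail_fraction
        self.seed = seed

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in (
            "outcome", "mediator", "treatment", "covariates", "family",
            "n_resamples", "inference", "n_point_draws", "t0", "t1",
            "max_fail_fraction", "seed")}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, df: pd.DataFrame):
        if self.t1 - self.t0 != 1.0:
            raise ValueError("treatment contrast must be a 1-SD shift (t1-t0=1)")
        if self.n_resamples < 100:
            raise ValueError("n_resamples must be >= 100")
        covs = DEFAULT_COVARIATES if self.covariates is None else self.covariates
        cols = [self.outcome, self.mediator, self.treatment, *covs]
        sub = df[cols].dropna()
        y = sub[self.outcome].to_numpy(dtype=float)
        M = sub[self.mediator].to_numpy(dtype=float)
        T = sub[self.treatment].to_numpy(dtype=float)
        X = sub[covs].to_numpy(dtype=float)
        fam = self.family
        if fam == "auto":
            fam = "logistic" if set(np.unique(y)) <= {0.0, 1.0} else "linear"
        n = len(y)
        rng = np.random.default_rng(self.seed)

        coef_m, sigma_m, coef_y, cov_y, Dm, Dy = _fit_models(T, M, y, X, fam)
        acme, ade, total = _effects(
            coef_m, sigma_m, coef_y, X, fam, rng, self.t0, self.t1,
            n_draws=self.n_point_draws,
        )

        draws = np.empty((self.n_resamples, 3))
        n_fail = 0
        if self.inference == "bootstrap":
            for bidx in range(self.n_resamples):
                idx = rng.integers(0, n, size=n)
                try:
                    cm, sm, cy, _, _, _ = _fit_models(
                        T[idx], M[idx], y[idx], X[idx], fam
                    )
                except ConvergenceError:
                    n_fail += 1
                    draws[bidx] = np.nan
                    continue
                a_, d_, t_ = _effects(cm, sm, cy, X[idx], fam, rng,
                                      self.t0, self.t1)
                draws[bidx] = (a_, d_, t_)
        elif self.inference == "quasi-bayesian":
            # parameter draws from the asymptotic normal of both fits
            cov_m = np.linalg.inv(Dm.T @ Dm) * sigma_m**2
            if cov_y is None:
                resid_y = y - Dy @ coef_y
                s2 = resid_y @ resid_y / (n - Dy.shape[1])
                cov_y = np.linalg.inv(Dy.T @ Dy) * s2
            Lm = np.linalg.cholesky(cov_m)
            Ly = np.linalg.cholesky(cov_y)
            for bidx in range(self.n_resamples):
                cm = coef_m + Lm @ rng.standard_normal(len(coef_m))
                cy = coef_y + Ly @ rng.standard_normal(len(coef_y))
                a_, d_, t_ = _effects(cm, sigma_m, cy, X, fam, rng,
                                      self.t0, self.t1)
                draws[bidx] = (a_, d_, t_)
        else:
            raise ValueError(f"unknown inference mode {self.inference!r}")

        if n_fail > self.max_fail_fraction * self.n_resamples:
            raise InferenceError(
                f"{n_fail}/{self.n_resamples} resample refits failed"
            )
        draws = draws[~np.isnan(draws).any(axis=1)]
        self.draws_ = draws  # columns: acme, ade, total (resample scale)
        acme_d, ade_d, total_d = draws[:, 0], draws[:, 1], draws[:, 2]

        def ci(x):
            return tuple(np.percentile(x, [2.5, 97.5]))

        prop = None
        if np.all(total_d > 0) or np.all(total_d < 0):
            prop = float(acme / total)

        self.total_, self.ade_, self.acme_ = float(total), float(ade), float(acme)
        self.family_ = fam
        self.n_ = n
        self.result_ = MediationResult(
            outcome=self.outcome,
            family=fam,
            total=float(total),
            ade=float(ade),
            acme=float(acme),
            total_ci=ci(total_d),
            ade_ci=ci(ade_d),
            acme_ci=ci(acme_d),
            total_p=_resample_p(total_d),
            ade_p=_resample_p(ade_d),
            acme_p=_resample_p(acme_d),
            proportion_mediated=prop,
            n=n,
            n_resamples=len(draws),
            inference=self.inference,
        )
        return self


def estimate_mediation(df: pd.DataFrame, outcome: str, **kwargs) -> MediationResult:
    """Functional wrapper over :class:`CausalMediation`."""
    est = CausalMediation(outcome=outcome, **kwargs)
    return est.fit(df).result_


def mediation_report(results: list[MediationResult],
                     ages: dict[str, int] | None = None) -> pd.DataFrame:
    """Tabulate mediation decompositions, one row per outcome.

    The ``total`` column equals ``ade + acme`` by construction of the
    averaged decomposition.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "phenotype": r.outcome,
                "age": (ages or {}).get(r.outcome),
                "total": r.total,
                "total_ci_low": r.total_ci[0],
                "total_ci_high": r.total_ci[1],
                "total_p": r.total_p,
                "ade": r.ade,
                "ade_ci_low": r.ade_ci[0],
                "ade_ci_high": r.ade_ci[1],
                "ade_p": r.ade_p,
                "acme": r.acme,
                "acme_ci_low": r.acme_ci[0],
                "acme_ci_high": r.acme_ci[1],
                "acme_p": r.acme_p,
                "proportion_mediated": r.proportion_mediated,
                "n": r.n,
            }
        )
    cols = ["phenotype", "age", "total", "total_ci_low", "total_ci_high",
            "total_p", "ade", "ade_ci_low", "ade_ci_high", "ade_p", "acme",
            "acme_ci_low", "acme_ci_high", "acme_p", "proportion_mediated", "n"]
    return pd.DataFrame(rows, columns=cols)
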