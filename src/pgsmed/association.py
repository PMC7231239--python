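"""Covariate-adjusted association estimates for the score.

Logistic models for binary disordered-eating behaviours (odds ratio per
1-SD score) and linear models for the continuous cognitions (beta per 1-SD
score), always adjusting for sex and the first four ancestry principal
components, on complete-case rows.  Includes the score-by-sex interaction
test with companion sex-stratified fits, and BH-FDR across phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .threshold import bh_fdr, liability_r2, nagelkerke_r2

DEFAULT_COVARIATES = ["sex", "pc1", "pc2", "pc3", "pc4"]


class SeparationError(RuntimeError):
    """Complete separation in a logistic fit; no penalized fallback."""


@dataclass
class AssociationResult:
    outcome: str
    family: str                  # "logistic" or "linear"
    effect: float                # OR per 1-SD (logistic) or beta (linear)
    ci95: tuple[float, float]
    p: float
    r2_observed: float
    r2_liability: float | None
    n: int
    n_cases: int | None = None
    n_controls: int | None = None
    q: float | None = None


def _design(df: pd.DataFrame, score: np.ndarray, covariates: list[str]):
    X = pd.DataFrame({"score": score}, index=df.index)
    for c in covariates:
        X[c] = df[c].to_numpy(dtype=float)
    return sm.add_constant(X[["score"] + covariates], has_constant="add")


def fit_association(
    df: pd.DataFrame,
    outcome: str,
    std_score: np.ndarray,
    covariates: list[str] | None = None,
    family: str = "auto",
) -> AssociationResult:
    """Fit ``outcome ~ score + covariates`` on complete cases.

    For binary outcomes the effect is the odds ratio per 1-SD score with a
    Wald 95% CI; the incremental Nagelkerke pseudo-R2 is converted to the
    liability scale using the sample case fraction as prevalence.  For
    continuous outcomes the effect is the raw-scale beta per 1-SD score and
    the incremental squared multiple correlation is reported.
    """
    covariates = DEFAULT_COVARIATES if covariates is None else covariates
    y_all = df[outcome].to_numpy(dtype=float)
    ok = ~np.isnan(y_all)
    ok &= ~df[covariates].isna().any(axis=1).to_numpy()
    ok &= ~np.isnan(np.asarray(std_score, dtype=float))
    sub = df.loc[ok]
    y = y_all[ok]
    s = np.asarray(std_score, dtype=float)[ok]
    if family == "auto":
        family = "logistic" if set(np.unique(y)) <= {0.0, 1.0} else "linear"
    X = _design(sub, s, covariates)
    X0 = X.drop(columns="score")
    n = len(y)
    if family == "logistic":
        try:
            full = sm.Logit(y, X).fit(disp=0, maxiter=100)
            cov_only = sm.Logit(y, X0).fit(disp=0, maxiter=100)
            null = sm.Logit(y, np.ones((n, 1))).fit(disp=0)
        except Exception as exc:  # pragma: no cover - statsmodels raises varied types
            raise SeparationError(str(exc)) from exc
        if not full.mle_retvals.get("converged", True) or np.abs(
            full.params
        ).max() > 40:
            raise SeparationError(f"logistic fit for {outcome!r} did not converge")
        b = full.params["score"]
        se = full.bse["score"]
        r2 = nagelkerke_r2(null.llf, full.llf, n) - nagelkerke_r2(
            null.llf, cov_only.llf, n
        )
        P = float(y.mean())
        return AssociationResult(
            outcome=outcome,
            family="logistic",
            effect=float(np.exp(b)),
            ci95=(float(np.exp(b - 1.96 * se)), float(np.exp(b + 1.96 * se))),
            p=float(full.pvalues["score"]),
            r2_observed=float(r2),
            r2_liability=liability_r2(r2, P, P),
            n=n,
            n_cases=int(y.sum()),
            n_controls=int(n - y.sum()),
        )
    full = sm.OLS(y, X).fit()
    cov_only = sm.OLS(y, X0).fit()
    b = full.params["score"]
    se = full.bse["score"]
    return AssociationResult(
        outcome=outcome,
        family="linear",
        effect=float(b),
        ci95=(float(b - 1.96 * se), float(b + 1.96 * se)),
        p=float(full.pvalues["score"]),
        r2_observed=float(full.rsquared - cov_only.rsquared),
        r2_liability=None,
        n=n,
    )


@dataclass
class SexInteractionResult:
    outcome: str
    interaction_coef: float
    interaction_p: float
    stratified: dict  # sex level -> AssociationResult


def sex_interaction(
    df: pd.DataFrame,
    outcome: str,
    std_score: np.ndarray,
    covariates: list[str] | None = None,
    family: str = "auto",
) -> SexInteractionResult:
    """Score-by-sex interaction (Wald p for the product term) with
    companion sex-stratified fits."""
    covariates = DEFAULT_COVARIATES if covariates is None else covariates
    if "sex" not in covariates:
        covariates = ["sex"] + covariates
    if df["sex"].nunique() < 2:
        raise ValueError("both sexes must be present for the interaction test")
    y_all = df[outcome].to_numpy(dtype=float)
    ok = ~np.isnan(y_all)
    ok &= ~df[covariates].isna().any(axis=1).to_numpy()
    ok &= ~np.isnan(np.asarray(std_score, dtype=float))
    sub = df.loc[ok]
    y = y_all[ok]
    s = np.asarray(std_score, dtype=float)[ok]
    if family == "auto":
        family = "logistic" if set(np.unique(y)) <= {0.0, 1.0} else "linear"
    X = _design(sub, s, covariates)
    X["score_x_sex"] = X["score"] * X["sex"]
    model = sm.Logit if family == "logistic" else sm.OLS
    fit = model(y, X).fit(disp=0) if family == "logistic" else model(y, X).fit()
    strat = {}
    for level in sorted(sub["sex"].unique()):
        mask = (sub["sex"] == level).to_numpy()
        strat[int(level)] = fit_association(
            sub.loc[mask],
            outcome,
            s[mask],
            covariates=[c for c in covariates if c != "sex"],
            family=family,
        )
    return SexInteractionResult(
        outcome=outcome,
        interaction_coef=float(fit.params["score_x_sex"]),
        interaction_p=float(fit.pvalues["score_x_sex"]),
        stratified=strat,
    )


def fdr_across_phenotypes(results: list[AssociationResult]) -> list[AssociationResult]:
    """Attach BH-FDR Q-values across the supplied family of phenotype tests."""
    if not results:
        return results
    q = bh_fdr([r.p for r in results])
    for r, qi in zip(results, q):
        r.q = float(qi)
    return results


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Report table mirroring the per-outcome association summary."""
    rows = []
    for r in results:
        rows.append(
            {
                "outcome": r.outcome,
                "family": r.family,
                "effect": r.effect,
                "ci_low": r.ci95[0],
                "ci_high": r.ci95[1],
                "p": r.p,
                "q": r.q,
                "r2_observed": r.r2_observed,
                "r2_liability": r.r2_liability,
                "n": r.n,
                "n_cases": r.n_cases,
                "n_controls": r.n_controls,
            }
        )
    return pd.DataFrame(rows)
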