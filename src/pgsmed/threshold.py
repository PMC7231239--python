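"""High-resolution p-value-threshold optimization.

For each discovery p-value cutoff Pt on a dense grid the clumped score is
rebuilt, the outcome regressed on score + covariates, and the incremental
model fit recorded (Nagelkerke pseudo-R2 difference for binary outcomes,
squared-multiple-correlation difference for continuous ones).  The best-fit
threshold maximizes R2.  Because scanning a grid and picking the maximum
overfits, a permutation empirical p-value (outcome labels permuted, full
grid rescanned each time) accompanies the best fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from ._glm import (
    ConvergenceError,
    linear_partial_f_test,
    logistic_irls,
    logistic_loglik,
    rao_score_test,
)
from .io import GenotypeMatrix
from .pgs import HarmonizedPanel

logger = logging.getLogger("pgsmed")


def default_grid() -> np.ndarray:
    """Dense threshold grid: {5e-8, 1e-6, 1e-5} then 1e-4 .. 1 by 1e-4."""
    return np.concatenate(
        [[5e-8, 1e-6, 1e-5], np.arange(1e-4, 1.0 + 1e-12, 1e-4)]
    )


def nagelkerke_r2(loglik_null: float, loglik_full: float, n: int) -> float:
    """Nagelkerke pseudo-R2 from null and full log-likelihoods.

    [1 - exp((2/n)(ll0 - ll1))] / [1 - exp((2/n) ll0)].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if loglik_full < loglik_null - 1e-8:
        raise ValueError("full-model likelihood below null likelihood")
    denom = 1.0 - np.exp((2.0 / n) * loglik_null)
    if denom == 0:
        raise ZeroDivisionError("degenerate null likelihood (denominator 0)")
    num = 1.0 - np.exp((2.0 / n) * (loglik_null - loglik_full))
    return float(num / denom)


def liability_r2(r2_observed: float, prevalence_k: float,
                 case_fraction_p: float) -> float:
    """Convert an observed-scale pseudo-R2 to the liability scale.

    Multiplier C = K^2 (1-K)^2 / (z^2 P (1-P)) with z the standard-normal
    density at the K-quantile threshold.  With K = P (population sample)
    this reduces to K(1-K)/z^2.
    """
    K, P = prevalence_k, case_fraction_p
    if not (0 < K < 1 and 0 < P < 1):
        raise ValueError("prevalence and case fraction must lie in (0,1)")
    z = stats.norm.pdf(stats.norm.ppf(K))
    C = (K * K * (1 - K) ** 2) / (z * z * P * (1 - P))
    return float(r2_observed * C)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted Q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ThresholdScanResult:
    """Per-threshold fit surface plus the best fit and its empirical p."""

    table: pd.DataFrame  # threshold, n_snps, r2_observed, p
    best_threshold: float
    best_n_snps: int
    best_r2_observed: float
    best_r2_liability: float | None
    empirical_p: float | None = None
    n_permutations: int = 0


def _prepare_rows(outcome, covariates):
    y = np.asarray(outcome, dtype=float)
    X = np.column_stack([np.ones(len(y)), np.asarray(covariates, dtype=float)])
    ok = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    return y, X, ok


def _score_matrix(panel: HarmonizedPanel, geno: GenotypeMatrix,
                  grid: np.ndarray):
    """Raw scores at every distinct SNP-count cutpoint implied by the grid.

    Returns (counts_per_threshold, unique_counts, S) where S[:, t] is the
    raw score using the unique_counts[t] smallest-p variants.
    """
    t = panel.table.sort_values(["P", "BP", "SNP"], kind="mergesort")
    p_sorted = t["P"].to_numpy()
    counts = np.searchsorted(p_sorted, grid, side="right")
    uniq = np.unique(counts)
    d = geno.dosage[:, t["geno_index"].to_numpy()]
    eff = np.where(t["flipped"].to_numpy(), 2.0 - d, d)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(eff, axis=0) / 2.0
    eff = np.where(np.isnan(eff), 2.0 * np.nan_to_num(freq), eff)
    contrib = eff * t["BETA"].to_numpy()
    nz = uniq[uniq > 0]
    if nz.size:
        # prefix sums at each cutpoint (truncate so the last reduceat
        # segment ends exactly at the largest cutpoint)
        seg = np.add.reduceat(contrib[:, : nz[-1]], np.r_[0, nz[:-1]], axis=1)
        cum = np.cumsum(seg, axis=1)
    S = np.zeros((geno.n_samples, uniq.size))
    S[:, uniq > 0] = cum if nz.size else 0.0
    return counts, uniq, S


class ThresholdScan(BaseEstimator):
    """Threshold-optimized PGS association, sklearn-style.

    ``fit(panel, genotypes, outcome, covariates)`` scans the grid and sets
    ``results_``, ``best_threshold_``, ``best_r2_observed_``,
    ``best_r2_liability_`` (binary outcomes) and, when ``n_perm > 0``,
    ``empirical_p_``.  ``family`` is ``"auto"`` (binary iff the outcome has
    two levels), ``"logistic"`` or ``"linear"``.  ``prevalence_k`` overrides
    the population prevalence used for the liability conversion (defaults to
    the sample case fraction).
    """

    def __init__(self, grid=None, family: str = "auto", n_perm: int = 0,
                 prevalence_k: float | None = None, seed: int = 0):
        self.grid = grid
        self.family = family
        self.n_perm = n_perm
        self.prevalence_k = prevalence_k
        self.seed = seed

    # -- internals -----------------------------------------------------

    def _resolve(self, y):
        grid = np.sort(np.atleast_1d(
            default_grid() if self.grid is None else np.asarray(self.grid, float)
        ))
        fam = self.family
        if fam == "auto":
            fam = "logistic" if set(np.unique(y)) <= {0.0, 1.0} else "linear"
        return grid, fam

    def fit(self, panel: HarmonizedPanel, genotypes: GenotypeMatrix,
            outcome, covariates):
        y_all, X_all, ok = _prepare_rows(outcome, covariates)
        y, X0 = y_all[ok], X_all[ok]
        if np.unique(y).size < 2:
            raise ValueError("outcome is constant on complete-case rows")
        grid, fam = self._resolve(y)
        counts, uniq, S_all = _score_matrix(panel, genotypes, grid)
        S = S_all[ok]
        sd = S.std(axis=0)
        Sz = np.where(sd > 0, (S - S.mean(axis=0)) / np.where(sd == 0, 1, sd), 0.0)

        n = len(y)
        r2 = np.zeros(uniq.size)
        pvals = np.ones(uniq.size)
        if fam == "logistic":
            b_null_only, ll_null, _ = logistic_irls(np.ones((n, 1)), y)
            b_cov, ll_cov, _ = logistic_irls(X0, y)
            r2_cov = nagelkerke_r2(ll_null, ll_cov, n)
            warm = np.r_[b_cov, 0.0]
            for t in range(uniq.size):
                if sd[t] == 0:
                    continue
                Xf = np.column_stack([X0, Sz[:, t]])
                try:
                    b, ll, cov = logistic_irls(Xf, y, beta0=warm)
                except ConvergenceError:
                    logger.warning("scan: fit failed at count %d", uniq[t])
                    continue
                warm = b
                r2[t] = nagelkerke_r2(ll_null, ll, n) - r2_cov
                zstat = b[-1] / np.sqrt(cov[-1, -1])
                pvals[t] = 2 * stats.norm.sf(abs(zstat))
        else:
            Q, _ = np.linalg.qr(X0)
            ry = y - Q @ (Q.T @ y)
            RS = Sz - Q @ (Q.T @ Sz)
            # incremental R^2 = squared semi-partial correlation: the extra
            # explained SS over the total (centred) SS of the outcome
            sst = float(np.sum((y - y.mean()) ** 2))
            num = RS.T @ ry
            den = np.einsum("ij,ij->j", RS, RS)
            good = den > 1e-12
            r2[good] = (num[good] ** 2) / (den[good] * sst)
            pvals = linear_partial_f_test(X0, y, Sz)
            pvals[~good] = 1.0

        best_t = int(np.argmax(r2))
        best_count = uniq[best_t]
        # smallest grid threshold attaining the best SNP count
        best_threshold = float(grid[np.argmax(counts == best_count)])
        table = pd.DataFrame(
            {
                "threshold": grid,
                "n_snps": counts,
                "r2_observed": r2[np.searchsorted(uniq, counts)],
                "p": pvals[np.searchsorted(uniq, counts)],
            }
        )
        r2_liab = None
        if fam == "logistic":
            P = float(y.mean())
            K = self.prevalence_k if self.prevalence_k is not None else P
            r2_liab = liability_r2(r2[best_t], K, P)

        emp_p = None
        if self.n_perm:
            emp_p = self._permute(X0, y, Sz, sd, fam)
        self.results_ = ThresholdScanResult(
            table=table,
            best_threshold=best_threshold,
            best_n_snps=int(best_count),
            best_r2_observed=float(r2[best_t]),
            best_r2_liability=r2_liab,
            empirical_p=emp_p,
            n_permutations=self.n_perm if emp_p is not None else 0,
        )
        self.best_threshold_ = best_threshold
        self.best_r2_observed_ = float(r2[best_t])
        self.best_r2_liability_ = r2_liab
        self.empirical_p_ = emp_p
        self.family_ = fam
        return self

    def _permute(self, X0, y, Sz, sd, fam) -> float:
        """Empirical p for the best fit: permute outcome labels, rescan the
        whole grid, compare best per-threshold p-values.

        The per-threshold statistic here (for both the observed data and the
        permutations) is a Rao score test (binary) or partial F-test
        (continuous) for adding the score to the covariate model —
        asymptotically the model p of the full fit, but cheap enough to
        evaluate across the full grid thousands of times.
        """
        rng = np.random.default_rng(self.seed)
        use = sd > 0
        if not np.any(use):
            return 1.0
        S_use = Sz[:, use]
        if fam == "logistic":
            obs_best = np.min(rao_score_test(X0, y, S_use))
        else:
            obs_best = np.min(linear_partial_f_test(X0, y, S_use))
        n_hit = 0
        for _ in range(self.n_perm):
            yp = rng.permutation(y)
            try:
                if fam == "logistic":
                    perm_best = np.min(rao_score_test(X0, yp, S_use))
                else:
                    perm_best = np.min(linear_partial_f_test(X0, yp, S_use))
            except ConvergenceError:
                perm_best = 0.0  # count failures as extreme (conservative)
            n_hit += perm_best <= obs_best
        return float((1 + n_hit) / (self.n_perm + 1))


def scan(panel, genotypes, outcome, covariates, grid=None, family="auto",
         prevalence_k=None) -> ThresholdScanResult:
    """Functional wrapper over :class:`ThresholdScan` (no permutations)."""
    est = ThresholdScan(grid=grid, family=family, prevalence_k=prevalence_k)
    return est.fit(panel, genotypes, outcome, covariates).results_


def permutation_empirical_p(panel, genotypes, outcome, covariates, grid=None,
                            n_perm: int = 11_000, seed: int = 0,
                            family: str = "auto") -> float:
    """Empirical p-value of the best-fit threshold via label permutation."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    est = ThresholdScan(grid=grid, family=family, n_perm=n_perm, seed=seed)
    est.fit(panel, genotypes, outcome, covariates)
    return est.empirical_p_
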