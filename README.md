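# pgsmed

Polygenic-score epidemiology of adolescent disordered eating, end to end:
from discovery GWAS summary statistics to causal mediation through
childhood body-mass index.

`pgsmed` is a tested, reusable implementation of the analytic chain used to
ask whether genetic liability for higher BMI is associated with disordered
eating (DE) — fasting, binge eating and purging at ages 14/16/18, and DE
cognitions such as body dissatisfaction at 14 — and whether that
association runs through measured childhood BMI.  It is aimed at
statistical geneticists and epidemiologists who want each stage of such an
analysis available as a library component with known behaviour on
synthetic ground truth.

## What it computes

1. **Clumping + thresholding (C+T) polygenic scores.**  Strand-ambiguous
   (A/T, C/G) variants are removed, discovery and target panels are
   harmonized by variant id with effect-allele orientation against the
   target REF/ALT, and greedy p-value-ordered LD clumping retains the
   smallest-p SNP in each ±250 kb window, pruning neighbours with
   r² > 0.1.  The score for individual *i* is the weighted allele sum
   `PGS_i = Σ_j β_j d_ij` over SNPs with discovery `p ≤ P_t`, standardized
   to mean 0, SD 1 in the sample.
2. **High-resolution threshold optimization.**  For a dense grid of
   thresholds the incremental model fit of `outcome ~ PGS + sex + PC1..4`
   is recorded — Nagelkerke pseudo-R²
   `[1 − exp((2/n)(ℓ₀ − ℓ₁))]/[1 − exp((2/n)ℓ₀)]` for binary outcomes
   (converted to the liability scale with the multiplier
   `K²(1−K)²/(z²P(1−P))`), incremental squared multiple correlation for
   continuous ones.  Because maximizing over a grid overfits, the best fit
   carries a permutation empirical p-value (outcome labels permuted, the
   entire grid rescanned each time).
3. **Association models.**  Odds ratios per 1-SD score (logistic) and
   betas per 1-SD score (linear), Wald 95% CIs, score-by-sex interaction
   with sex-stratified fits, and Benjamini–Hochberg FDR across phenotypes.
4. **Longitudinal GLMM.**  A random-intercept logistic model
   `logit P(y_it) = x_itβ + b_i`, `b_i ~ N(0, σ²)`, fitted by adaptive
   Gauss–Hermite quadrature, tests whether the score–outcome association
   is age-dependent via a score×age interaction (score at `P_t = 1`).
5. **Counterfactual causal mediation.**  Natural direct and indirect
   effects of a 1-SD score shift with childhood zBMI as mediator: ACME
   (the mediated component), ADE (the direct component) and their sum, the
   total effect, as risk differences (binary) or mean differences
   (continuous), with bootstrap or quasi-Bayesian inference.  By
   construction `total = ADE + ACME` exactly.
6. **Synthetic cohort generator.**  Block-LD genotypes (Gaussian copula,
   5 kb spacing), a GIANT-style discovery summary file with configurable
   strand-ambiguity and allele flips, and a phenotype table with the
   score → zBMI → outcome structure, per-wave outcome prevalences,
   age/sex-standardized zBMI, five-level frequency items with a
   loss-of-control gate for binge eating, and missing-at-random attrition
   driven by sex and the score.

## Worked example

```python
from pgsmed import (SimulationConfig, simulate_study, PolygenicScorer,
                    ThresholdScan, fit_association, estimate_mediation)
from pgsmed.io import align_samples

cfg = SimulationConfig(n_individuals=6000, n_variants=1500, n_causal=150, seed=7)
sumstats, geno, cohort, truth = simulate_study(cfg)
geno, cohort = align_samples(geno, cohort)

scorer = PolygenicScorer().fit(sumstats, geno)          # QC + harmonize + clump
covs = cohort[["sex", "pc1", "pc2", "pc3", "pc4"]].to_numpy(float)

scan = ThresholdScan(n_perm=500, seed=7)
scan.fit(scorer.panel_, geno, cohort["fasting14"].to_numpy(float), covs)
print(f"best Pt={scan.best_threshold_:g}  "
      f"liability R2={scan.best_r2_liability_:.4f}  "
      f"empirical p={scan.empirical_p_:.4g}")

pgs = scorer.transform(p_threshold=scan.best_threshold_).std
assoc = fit_association(cohort, "fasting14", pgs)
print(f"OR per SD = {assoc.effect:.2f} "
      f"(95% CI {assoc.ci95[0]:.2f}, {assoc.ci95[1]:.2f})")

med = cohort.copy(); med["std_score"] = pgs
r = estimate_mediation(med, "fasting14", n_resamples=500, seed=7)
print(f"total={r.total:.4f}  ADE={r.ade:.4f}  ACME={r.acme:.4f}")
```

Output (seed 7):

```
best Pt=0.0146  liability R2=0.0638  empirical p=0.001996
OR per SD = 1.40 (95% CI 1.26, 1.57)
total=0.0244  ADE=0.0145  ACME=0.0099
```

Read: one SD of score multiplies the odds of monthly fasting by ~1.4, and
no permutation of the outcome produced a grid-wide fit that strong; of the
~2.4 percentage-point total risk difference, about 40% flows through
childhood zBMI (the ACME) and the rest is direct.

A CLI mirrors the stages (`pgsmed simulate`, `pgsmed score`,
`pgsmed scan`, `pgsmed pipeline run --config run.yaml`).

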