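# Methods

This note documents the models implemented in `pgsmed`, the assumptions
behind them, the defaults of the synthetic-data generator, and the
numerical choices that matter for reproducing results.

## Scientific setting

The package implements the analytic chain linking a BMI polygenic score
(PGS) to adolescent disordered-eating (DE) outcomes in a birth cohort:
binary behaviours (fasting, binge eating, purging) self-reported at ages
14, 16 and 18; continuous cognitions (thin-ideal internalization, body
dissatisfaction, restrained/emotional/external eating) at 14; and
childhood BMI, age- and sex-standardized (zBMI), measured at 11 — before
the outcomes, which is what makes it a usable mediator.

## Polygenic scoring (C+T)

*QC and harmonization.*  Strand-ambiguous SNPs (allele pair A/T or C/G)
are removed before anything else: their orientation cannot be resolved
across strand conventions.  Remaining variants are matched between
discovery and target **by id**; when the discovery effect allele equals
the target ALT the dosage is used as-is, when it equals REF the
effect-allele dosage is `2 − d`, and any other pair is dropped with a
logged count.  Position+allele matching would be a possible extension; id
matching keeps the bookkeeping transparent.  Indels and multi-allelic
records are excluded (SNP-only analysis).

*Clumping.*  Greedy, p-value ordered: the unpruned variant with the
smallest discovery p becomes an index; every unpruned variant on the same
chromosome within ±250 kb (inclusive) with r² > 0.1 against it is pruned
and attributed to that index; repeat until exhausted.  The window is
interpreted as ±250 kb around the index, the common clumping convention.
r² is the squared Pearson correlation of dosages computed **in the target
sample** over pairwise-complete individuals — no external LD reference, so
the artifact is self-contained.  Ties on p are broken by smaller position,
then lexicographic id, which makes the result invariant to input order
(verified by test).  Monomorphic variants get r² = 0 and are retained;
their score contribution is a constant absorbed by standardization.

*Scoring.*  `raw_i = Σ_j β_j d_ij` over panel SNPs with `p ≤ P_t`; missing
dosages are mean-imputed with `2 ×` the **target-sample** effect-allele
frequency (always available, unlike discovery EAF).  The standardized
score is `(raw − mean)/SD` over the sample; with zero passing variants the
score is defined as all-zero with a warning.

## Threshold optimization and fit statistics

The fit surface is evaluated on a dense grid (default
`{5·10⁻⁸, 10⁻⁶, 10⁻⁵} ∪ {10⁻⁴, 2·10⁻⁴, …, 1}`); thresholds that admit
identical SNP sets are computed once.  The reported statistic is
**incremental** fit — full model minus covariates-only model — so that
sex and ancestry PCs never inflate the score's apparent contribution:

- binary: difference of Nagelkerke pseudo-R²,
  `R² = [1 − exp((2/n)(ℓ₀−ℓ₁))]/[1 − exp((2/n)ℓ₀)]`, both models
  referenced to the intercept-only likelihood ℓ₀;
- continuous: difference in squared multiple correlation, equal to the
  squared semi-partial correlation of the score.

The best threshold maximizes R² (minimizing the model p is equivalent for
this one-parameter comparison except in edge cases; maximizing R² is what
is implemented).

*Liability scale.*  For binary outcomes the observed-scale R² is
multiplied by `K²(1−K)² / (z² P(1−P))`, with K the population prevalence,
P the sample case fraction and z the standard-normal density at the
K-quantile.  In a population cohort the analysis sample is not
case-control ascertained, so K defaults to P (the multiplier reduces to
`K(1−K)/z²`); an external prevalence can be supplied.

*Permutation empirical p.*  Selecting the maximum over a grid overfits:
with null data the naive best-fit p is grossly anti-conservative (shown in
the test suite).  The empirical p permutes outcome labels (covariates stay
attached to individuals), rescans the entire grid per permutation, and
compares best p-values: `(1 + #{perm best ≤ observed best})/(n_perm + 1)`.
The default is 11,000 permutations; the test suite and acceptance script
use 199–1,000 to keep desk-scale runtimes.  Inside the permutation engine
the per-threshold p (for the observed data and every permutation alike) is
a Rao score test of the score term given the covariate-model fit — it is
asymptotically the model p of the full fit but needs only one null
logistic fit per permutation plus vectorized linear algebra across
thresholds, which is what makes thousands of grid rescans tractable.  The
reported scan table itself comes from full maximum-likelihood fits.

## Association models

Logistic (binary) or linear (continuous) regression of each outcome on
the standardized best-fit score plus sex and four ancestry PCs, on
complete cases per outcome.  Effects are reported per 1-SD of score: the
odds ratio `exp(β̂)` with Wald 95% CIs (conventional for PGS reporting),
or the raw-scale beta for continuous outcomes (only the score is
standardized, not the outcome).  Complete separation raises an error
rather than silently falling back to penalization.  BH-FDR Q-values are
attached across the family of phenotypes tested.  The score×sex
interaction is a Wald test on the product term, with companion
sex-stratified fits.

## Longitudinal random-intercept model

`logit P(y_it=1) = β₀ + b_i + β₁·PGS_i + β₂·age_t + β₃·PGS_i·age_t +
βₓ·covariates`, `b_i ~ N(0, σ²)`, with the score fixed at `P_t = 1` so the
same quantity enters at every age.  Age is linear (categorical age is a
possible option), centred at 14 and scaled to 2-year units {0,1,2} for
conditioning; age terms are rescaled to per-year effects for reporting.
The marginal likelihood integrates b_i out per person with **adaptive**
Gauss–Hermite quadrature (default 11 nodes, ≥9): the integrand is
re-centred at each person's posterior mode (found by damped Newton, the
integrand being concave) and rescaled by its curvature, then summed in the
log domain.  Quadrature was chosen over quasi-Monte-Carlo integration for
bit-reproducibility and speed with a single random effect.  The outer
optimization is L-BFGS-B over (β, log σ) with log σ bounded in [−6, 3];
at the lower bound the model degenerates cleanly to plain logistic
regression (verified against a direct fit).  Wald SEs come from a
central-difference observed-information matrix; when log σ sits on its
boundary that direction is flat and the β block is inverted alone.
Non-convergence triggers retries with more nodes and a rescaled start
before raising.

## Causal mediation

Natural direct/indirect effects of a 1-SD score contrast (t: 0 → 1 on the
standardized scale; the cohort is never dichotomized):

1. mediator model `M = α_m + aT + γ_mᵀX + ε`, `ε ~ N(0, σ²)` (OLS);
2. outcome model `Y ~ α_y + c'T + bM + γ_yᵀX` (logistic or linear),
   additive — no exposure–mediator interaction, matching the analysis
   being reproduced;
3. for every observed covariate profile, potential mediators M(0), M(1)
   are drawn from the mediator model *including residual noise* (one
   shared residual draw per profile, so the M(0)/M(1) contrast is exact in
   a), and model-implied outcomes Y(t, M(t′)) are averaged:
   `ACME(t) = mean_i[Y_i(t,M_i(1)) − Y_i(t,M_i(0))]`,
   `ADE(t) = mean_i[Y_i(1,M_i(t)) − Y_i(0,M_i(t))]`, each averaged over
   t ∈ {0,1}.  With this averaging, `total = ADE + ACME` holds **exactly**,
   not just asymptotically.
4. inference: nonparametric bootstrap (default, 1,000 resamples, both
   models refit per resample, one mediator draw per profile) or
   quasi-Bayesian parameter draws from the asymptotic normal of both fits
   (σ_m held at its estimate).  CIs are percentile; p-values are two-sided
   resample sign probabilities.  Point estimates use 100 mediator draws on
   the original fit to suppress Monte-Carlo noise.

Binary-outcome effects are risk differences via model-implied
probabilities; continuous ones are mean differences.  Proportion mediated
(ACME/total) is reported only when the total keeps one sign across all
resamples.  Identification rests on sequential ignorability; the test
suite demonstrates the predictable ACME bias when an unmeasured
mediator–outcome confounder is injected into the generator.  Covariate
profiles are the full empirical distribution, not a reference profile.

## Synthetic cohort generator

The generator is the test bed: every condition is fixed a priori and the
true effects are known.

- **Genotypes.**  Gaussian-copula LD blocks: per haplotype an
  equicorrelated latent normal (default within-block correlation 0.7,
  block size 50) thresholded at the Hardy–Weinberg allele-frequency
  quantile; dosage = sum of two haplotypes.  MAF uniform on [0.05, 0.5];
  fixed 5 kb spacing on one chromosome, so the ±250 kb clumping window
  spans 50 adjacent variants = one block.  Realized genotype correlation
  is somewhat below the latent value (binary thresholding attenuates);
  what the generator guarantees is strong within-block and null
  cross-block LD, which is what clumping consumes.
- **True score.**  `n_causal` (default 200 of 2,000) variants get effects
  `β_j ~ N(0, h²/(n_causal·2p_jq_j))` so the raw score has variance
  ≈ h² = 0.11 — consistent with the default mediator path via
  `a = √(h²/(1−h²)) ≈ 0.35`.
- **Discovery GWAS.**  Marginal effect = within-block LD smear of causal
  effects (empirical correlations, truncated below the ~4/√n sampling
  floor so unlinked variants are exactly null) plus noise of variance
  `1/(2p(1−p)N)` at N = 789,224; two-sided Wald p.  A configurable
  fraction of variants is relabelled strand-ambiguous (default 5%) and a
  fraction reports the REF allele as effect allele with the sign flipped
  (default 20%) to exercise QC and harmonization.
- **Phenotypes.**  zBMI = `a·S + N(0,1)`, re-standardized within sex
  stratum (disable via `standardize_mediator=False` for structural-scale
  studies).  Binary behaviours: latent logistic propensity
  `c'·S + b·zBMI + β_sex·sex` with the intercept calibrated by bisection
  on [−15, 15] (tolerance 10⁻⁴ on the probability scale) to per-wave
  target prevalences taken from the observed cases/respondents ratios
  (fasting 6.5/13.4/5.5%, binge 6.2/13.0/19.1%, purging 6.1/6.4% at the
  respective ages).  The same latent yields the five-level past-year
  frequency item (cutpoints fixed at −0.8/0/0.9/1.8 relative to the
  calibrated monthly boundary), so dichotomizing the ordinal at "at least
  once a month" reproduces the binary outcome exactly; binge eating
  additionally requires a loss-of-control flag (P = 0.7 among
  overeaters, folded into the calibration).  Continuous cognitions follow
  the linear analogue with unit residual SD, with negative path signs for
  thin-ideal internalization and external eating.  Default paths
  `a = 0.35`, `b = 0.55`, `c' = 0.18` split the total effect per 1-SD
  score about evenly between direct and mediated components, mirroring
  the published fasting-at-14 decomposition; `β_sex = 1.5` gives the
  strong female preponderance seen in DE behaviours.
- **Missingness.**  Cell-wise MAR:
  `P(miss) = expit(logit(rate) + δ_sex·sex + δ_PGS·S)` with defaults
  rate 0.2, δ_sex = −0.4, δ_PGS = +0.15 (attrition increases with the
  score).  Because the drivers (sex, score) are in every analysis model,
  complete-case estimates stay unbiased — asserted by test.
- **Determinism.**  One integer seed; every stage draws from a substream
  derived with a fixed label, so stages reproduce in isolation and
  identical configs give bit-identical outputs.

### What the generator does *not* emulate

Realistic human LD maps, imputation uncertainty, X chromosome,
relatedness, genuine population stratification (PCs are pure noise),
questionnaire measurement error, or missingness-not-at-random.  Passing
tests therefore establish the *statistical machinery* — calibration,
recovery, decomposition identities — not that real-cohort effect sizes
would be reproduced.  Observed associations of the fitted PGS are
attenuated relative to the generator's true-score paths in proportion to
the PGS/true-score correlation, exactly as a real PGS attenuates relative
to latent genetic liability.

## Problem sizes and defaults used for verification

The default study conditions are 8,654 individuals (the analysed-cohort
size), 2,000 variants in 40 LD blocks standing in for the genome-wide
panel, and a discovery N of 789,224.  The acceptance script runs those
defaults with 1,000 permutations and 1,000 bootstrap resamples.  The test
suite uses smaller replicates chosen for desk-scale runs: the mediation
linear oracle at n = 20,000 with 1,000 resamples, the binary
integration oracle at n = 10,000, permutation calibration with 200
procedure replicates at n_perm = 199 on a 50-point grid, and GLMM type-I
error over 200 replicates of 2,000 persons × 3 ages.

## Known limitations

- Id-based variant matching cannot rescue variants whose ids differ
  between panels.
- The liability conversion assumes the standard threshold model; K = P is
  only appropriate for population samples.
- The GLMM supports one random intercept (no random slopes) and a
  logistic link only.
- Mediation excludes exposure–mediator interactions and multiple
  mediators; no sensitivity-analysis ρ curves.
- Wald (not profile) CIs throughout.
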