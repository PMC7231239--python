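"""Synthetic cohort generator.

Emulates the three inputs of the analysis — a discovery GWAS summary file,
target-cohort genotypes with block LD, and an adolescent phenotype table with
binary disordered-eating (DE) behaviours at ages 14/16/18, continuous DE
cognitions at 14, and a childhood zBMI mediator — with a known causal
structure (score -> zBMI -> outcome plus a direct path) so that every
downstream stage can be tested against ground truth.

Genotypes use a Gaussian-copula block-LD model: per haplotype, an
equicorrelated latent normal per block is thresholded at the Hardy-Weinberg
allele-frequency quantile; dosage is the sum of two haplotypes.  Variants sit
at a fixed 5 kb spacing on one chromosome, so a 250 kb clumping window spans
50 adjacent variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .io import BINARY_OUTCOMES, CONTINUOUS_OUTCOMES, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "TrueModel",
    "simulate_genotypes",
    "draw_true_model",
    "simulate_discovery_sumstats",
    "simulate_cohort",
    "simulate_study",
    "dichotomize_frequency",
    "apply_mar_missingness",
    "ORDINAL_LEVELS",
]

#: YRBSS-style past-year frequency response options, least to most frequent
ORDINAL_LEVELS = [
    "Never",
    "Less than once a month",
    "1-3 times a month",
    "Once a week",
    "2 or more times a week",
]

#: observed per-wave prevalence (cases / respondents) used as defaults
DEFAULT_PREVALENCE = {
    "fasting14": 300 / 4584,
    "fasting16": 516 / 3844,
    "fasting18": 143 / 2586,
    "binge14": 257 / 4144,
    "binge16": 434 / 3336,
    "binge18": 365 / 1910,
    "purging16": 237 / 3871,
    "purging18": 166 / 2582,
}

#: sign of the genetic/mediator path for each continuous cognition
#: (thin-ideal internalization and external eating run negative)
CONTINUOUS_SIGNS = {
    "thin_ideal14": -1.0,
    "body_dissat14": 1.0,
    "restrained14": 1.0,
    "emotional14": 1.0,
    "external14": -1.0,
}

# fixed substream labels so stages are reproducible in isolation
_STREAM = {"genotypes": 1, "true_model": 2, "sumstats": 3, "cohort": 4, "mar": 5}


class CalibrationError(RuntimeError):
    """Prevalence target unreachable (intercept root not bracketed)."""


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAM[stage],))
    )


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Path parameters are chosen to emulate the published fasting-at-14
    structure: total effect per 1-SD score split about evenly between the
    direct path and the path mediated by childhood zBMI
    (``c_prime`` approximately ``b_path * a_path / sqrt(1 + a_path**2)``).
    """

    n_individuals: int = 8654
    n_variants: int = 2000
    n_causal: int = 200
    ld_block_size: int = 50
    within_block_r: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_score: float = 0.11     # variance of the raw true score (liability units)
    a_path: float = 0.35       # zBMI SD units per 1-SD true score
    b_path: float = 0.55       # outcome log-odds (or units) per 1-SD zBMI
    c_prime: float = 0.18      # direct outcome effect per 1-SD true score
    beta_sex: float = 1.5      # female (sex=1) log-odds shift for DE behaviours
    beta_sex_cont: float = 0.3
    loc_rate: float = 0.7      # P(loss of control | overeating) for binge
    prevalence_targets: dict = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    n_discovery: int = 789_224
    ambiguous_fraction: float = 0.05
    flip_fraction: float = 0.2  # sumstats reporting the REF allele as effect
    missing_rate: float = 0.2
    delta_sex: float = -0.4    # female -> less missingness
    delta_pgs: float = 0.15    # higher score -> more attrition
    standardize_mediator: bool = True
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if min(self.n_individuals, self.n_variants, self.ld_block_size) <= 0:
            raise ValueError("counts must be positive")
        if not 0 < self.n_causal <= self.n_variants:
            raise ValueError("n_causal must be in (0, n_variants]")
        if not 0 <= self.within_block_r < 1:
            raise ValueError("within_block_r must lie in [0, 1)")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_discovery <= 0:
            raise ValueError("n_discovery must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        for k, v in self.prevalence_targets.items():
            if not 0 < v < 1:
                raise ValueError(f"prevalence target {k}={v} outside (0,1)")
        return self


@dataclass
class TrueModel:
    """Ground truth behind one simulated study (non-causal betas are 0)."""

    causal_betas: np.ndarray
    true_score: np.ndarray
    a_path: float
    b_path: float
    c_prime: float

    @property
    def std_score(self) -> np.ndarray:
        s = self.true_score
        return (s - s.mean()) / s.std()


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw block-LD genotypes (values in {0,1,2}) on one chromosome."""
    config.validate()
    rng = _rng(config.seed, "genotypes")
    n, m = config.n_individuals, config.n_variants
    maf = rng.uniform(*config.maf_range, size=m)
    r = config.within_block_r
    block = np.repeat(np.arange(int(np.ceil(m / config.ld_block_size))),
                      config.ld_block_size)[:m]
    n_blocks = block[-1] + 1
    from scipy.stats import norm

    thresh = norm.ppf(maf)
    dosage = np.zeros((n, m))
    for _hap in range(2):
        shared = rng.standard_normal((n, n_blocks))[:, block]
        z = np.sqrt(r) * shared + np.sqrt(1 - r) * rng.standard_normal((n, m))
        dosage += (z < thresh).astype(float)

    # allele pairs: non-ambiguous by construction (REF/ALT never complementary)
    pair_choices = np.array([["A", "G"], ["A", "C"], ["T", "G"], ["T", "C"],
                             ["G", "A"], ["C", "A"], ["G", "T"], ["C", "T"]])
    pairs = pair_choices[rng.integers(0, len(pair_choices), size=m)]
    variants = pd.DataFrame(
        {
            "SNP": [f"rs{j + 1}" for j in range(m)],
            "CHR": "1",
            "BP": 1 + 5000 * np.arange(m),  # fixed 5 kb spacing
            "REF": pairs[:, 0],
            "ALT": pairs[:, 1],
        }
    )
    samples = [f"S{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(dosage, variants, samples)


def draw_true_model(geno: GenotypeMatrix, config: SimulationConfig) -> TrueModel:
    """Assign causal effects to ``n_causal`` variants and compute the latent
    per-individual genetic value.  Per-variant betas are scaled so the raw
    score variance is about ``h2_score`` (its share of a unit mediator
    liability)."""
    rng = _rng(config.seed, "true_model")
    m = geno.n_variants
    causal_idx = np.sort(rng.choice(m, size=config.n_causal, replace=False))
    p = np.clip(geno.alt_frequency(), 1e-6, 1 - 1e-6)
    betas = np.zeros(m)
    sd_j = np.sqrt(config.h2_score / (config.n_causal * 2 * p[causal_idx]
                                      * (1 - p[causal_idx])))
    betas[causal_idx] = rng.standard_normal(config.n_causal) * sd_j
    d = np.nan_to_num(geno.dosage, nan=0.0)
    score = d @ betas
    return TrueModel(betas, score, config.a_path, config.b_path, config.c_prime)


def simulate_discovery_sumstats(
    geno: GenotypeMatrix,
    true_model: TrueModel,
    n_discovery: int,
    seed: int,
    ambiguous_fraction: float = 0.0,
    flip_fraction: float = 0.0,
) -> pd.DataFrame:
    """Emulate a discovery-GWAS summary file over the simulated variants.

    Marginal effects are LD-smeared causal effects (within-block correlation
    times causal betas) plus sampling noise of variance 1/(2*maf*(1-maf)*N);
    p-values come from the two-sided Wald statistic.  ``ambiguous_fraction``
    relabels that exact fraction of variants with A/T or C/G pairs (QC bait);
    ``flip_fraction`` reports the REF allele as the effect allele (with the
    beta sign flipped accordingly) to exercise harmonization.
    """
    if n_discovery <= 0:
        raise ValueError("n_discovery must be positive")
    rng = _rng(seed, "sumstats")
    m = geno.n_variants
    maf = np.clip(geno.alt_frequency(), 0.01, 0.99)

    # LD-smeared marginal effects via empirical correlation with causal sites
    marginal = np.zeros(m)
    d = np.nan_to_num(geno.dosage, nan=0.0)
    causal = np.flatnonzero(true_model.causal_betas)
    sd = d.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    dz = (d - d.mean(axis=0)) / sd
    n = d.shape[0]
    # correlation of every variant with each causal variant (m x n_causal);
    # truncate values below the sampling-noise floor so unlinked variants
    # stay exactly null (the empirical correlation is only a stand-in for
    # the generator's true LD, which is zero across blocks)
    if causal.size:
        C = dz.T @ dz[:, causal] / n
        cut = max(0.05, 4.0 / np.sqrt(n))
        C[np.abs(C) < cut] = 0.0
        C[causal, np.arange(causal.size)] = 1.0
        marginal = C @ true_model.causal_betas[causal]
    se = 1.0 / np.sqrt(2 * maf * (1 - maf) * n_discovery)
    beta_hat = marginal + rng.standard_normal(m) * se
    from scipy.stats import norm

    pvals = 2 * norm.sf(np.abs(beta_hat / se))
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    a1 = geno.variants["ALT"].to_numpy().copy()
    a2 = geno.variants["REF"].to_numpy().copy()
    eaf = maf.copy()
    out_beta = beta_hat.copy()
    n_flip = int(round(flip_fraction * m))
    if n_flip:
        idx = rng.choice(m, size=n_flip, replace=False)
        a1[idx], a2[idx] = a2[idx].copy(), a1[idx].copy()
        out_beta[idx] = -out_beta[idx]
        eaf[idx] = 1 - eaf[idx]
    n_amb = int(round(ambiguous_fraction * m))
    if n_amb:
        idx = rng.choice(m, size=n_amb, replace=False)
        amb = np.array([["A", "T"], ["T", "A"], ["C", "G"], ["G", "C"]])
        pick = amb[rng.integers(0, 4, size=n_amb)]
        a1[idx], a2[idx] = pick[:, 0], pick[:, 1]
    return pd.DataFrame(
        {
            "SNP": geno.variants["SNP"],
            "CHR": geno.variants["CHR"],
            "BP": geno.variants["BP"],
            "A1": a1,
            "A2": a2,
            "EAF": eaf,
            "BETA": out_beta,
            "SE": se,
            "P": pvals,
        }
    )


def _calibrate_intercept(lp: np.ndarray, target: float, scale: float = 1.0,
                         tol: float = 1e-4) -> float:
    """Bisection for alpha s.t. mean(expit(alpha+lp))*scale = target."""

    def f(alpha: float) -> float:
        return float(np.mean(expit(alpha + lp))) * scale - target

    lo, hi = -15.0, 15.0
    if f(lo) > 0 or f(hi) < 0:
        raise CalibrationError(
            f"prevalence target {target} not bracketed on [-15, 15]"
        )
    return brentq(f, lo, hi, xtol=tol)


def _ordinal_from_latent(latent: np.ndarray) -> np.ndarray:
    """Map a calibrated latent propensity (0 = monthly boundary) to the five
    frequency levels; offsets are fixed relative to the monthly cutpoint."""
    cuts = np.array([-0.8, 0.0, 0.9, 1.8])  # <1/mo | 1-3/mo | weekly | >=2/wk
    idx = np.searchsorted(cuts, latent, side="left")
    return np.asarray(ORDINAL_LEVELS, dtype=object)[idx]


def dichotomize_frequency(ordinal, loss_of_control=None):
    """Dichotomize a past-year frequency response at ">= once a month".

    Returns 1 iff the response is at least "1-3 times a month"; for binge
    eating a positive response additionally requires ``loss_of_control``.
    Accepts scalars or array-likes; unknown levels raise ``ValueError``.
    """
    arr = np.atleast_1d(np.asarray(ordinal, dtype=object))
    rank = {lvl: i for i, lvl in enumerate(ORDINAL_LEVELS)}
    unknown = [x for x in arr if x not in rank]
    if unknown:
        raise ValueError(f"unknown frequency level(s): {sorted(set(map(str, unknown)))}")
    out = np.array([rank[x] >= 2 for x in arr], dtype=int)
    if loss_of_control is not None:
        loc = np.atleast_1d(np.asarray(loss_of_control)).astype(bool)
        out = out & loc.astype(int)
    return out if np.ndim(ordinal) else int(out[0])


def simulate_cohort(
    geno: GenotypeMatrix, true_model: TrueModel, config: SimulationConfig
) -> pd.DataFrame:
    """Draw the phenotype table from the structural model.

    zBMI at 11 is ``a_path * std(true score) + N(0,1)`` re-standardized
    within sex stratum (set ``standardize_mediator=False`` to keep the raw
    structural mediator).  Binary DE behaviours arise by thresholding a
    logistic latent propensity whose intercept is calibrated by bisection to
    the target prevalence; the same latent yields the five-level frequency
    item, and binge eating additionally requires a loss-of-control flag.
    Continuous cognitions follow the linear analogue with unit residual SD.
    """
    config.validate()
    rng = _rng(config.seed, "cohort")
    n = geno.n_samples
    S = true_model.std_score
    sex = rng.integers(0, 2, size=n).astype(float)  # 1 = female
    pcs = rng.standard_normal((n, 4))

    m_raw = true_model.a_path * S + rng.standard_normal(n)
    if config.standardize_mediator:
        zbmi = np.empty(n)
        for s in (0.0, 1.0):
            mask = sex == s
            x = m_raw[mask]
            zbmi[mask] = (x - x.mean()) / x.std()
    else:
        zbmi = m_raw

    tab = pd.DataFrame(
        {
            "sample_id": geno.samples,
            "sex": sex.astype(int),
            "pc1": pcs[:, 0],
            "pc2": pcs[:, 1],
            "pc3": pcs[:, 2],
            "pc4": pcs[:, 3],
            "zbmi11": zbmi,
            "true_score": S,  # latent ground truth, kept for testing only
        }
    )

    b, cp = true_model.b_path, true_model.c_prime
    for outcome in BINARY_OUTCOMES:
        target = config.prevalence_targets.get(outcome)
        if target is None:
            continue
        lp = cp * S + b * zbmi + config.beta_sex * sex
        is_binge = outcome.startswith("binge")
        scale = config.loc_rate if is_binge else 1.0
        alpha = _calibrate_intercept(lp, target, scale=scale)
        latent = alpha + lp + rng.logistic(size=n)
        freq = _ordinal_from_latent(latent)
        tab[outcome + "_freq"] = freq
        if is_binge:
            overeats = np.array([f != "Never" for f in freq])
            loc = np.zeros(n, dtype=bool)
            loc[overeats] = rng.random(overeats.sum()) < config.loc_rate
            tab[outcome + "_loc"] = loc
            tab[outcome] = dichotomize_frequency(freq, loc)
        else:
            tab[outcome] = dichotomize_frequency(freq)

    for outcome in CONTINUOUS_OUTCOMES:
        sign = CONTINUOUS_SIGNS[outcome]
        tab[outcome] = (
            sign * (cp * S + b * zbmi)
            + config.beta_sex_cont * sex
            + rng.standard_normal(n)
        )
    return tab


def apply_mar_missingness(
    cohort: pd.DataFrame,
    missing_rate: float,
    delta_sex: float = 0.0,
    delta_pgs: float = 0.0,
    seed: int = 0,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Blank outcome cells missing-at-random given sex and the score.

    Cell-wise missingness probability is
    ``expit(logit(missing_rate) + delta_sex*sex + delta_pgs*std_score)``.
    A ``miss_<col>`` indicator is stored per outcome; rows losing every
    outcome are dropped (the analysis keeps individuals with at least one
    outcome observed).
    """
    if missing_rate == 0:
        return cohort.copy()
    if not 0 < missing_rate < 1:
        raise ValueError("missing_rate must lie in (0,1)")
    rng = _rng(seed, "mar")
    out = cohort.copy()
    if columns is None:
        columns = [c for c in BINARY_OUTCOMES + CONTINUOUS_OUTCOMES
                   if c in out.columns]
    s = out["true_score"].to_numpy() if "true_score" in out else 0.0
    sex = out["sex"].to_numpy()
    p_miss = expit(logit(missing_rate) + delta_sex * sex + delta_pgs * s)
    for col in columns:
        miss = rng.random(len(out)) < p_miss
        out["miss_" + col] = miss.astype(int)
        out[col] = out[col].astype(float).mask(miss)
    outcome_cols = [c for c in BINARY_OUTCOMES + CONTINUOUS_OUTCOMES
                    if c in out.columns]
    all_missing = out[outcome_cols].isna().all(axis=1)
    if all_missing.any():
        out = out.loc[~all_missing].reset_index(drop=True)
    return out


def simulate_study(config: SimulationConfig):
    """Full generator: genotypes, truth, discovery sumstats, cohort (with
    MAR missingness applied).  Deterministic in ``config.seed``."""
    config.validate()
    geno = simulate_genotypes(config)
    truth = draw_true_model(geno, config)
    sumstats = simulate_discovery_sumstats(
        geno,
        truth,
        config.n_discovery,
        config.seed,
        ambiguous_fraction=config.ambiguous_fraction,
        flip_fraction=config.flip_fraction,
    )
    cohort = simulate_cohort(geno, truth, config)
    cohort = apply_mar_missingness(
        cohort,
        config.missing_rate,
        delta_sex=config.delta_sex,
        delta_pgs=config.delta_pgs,
        seed=config.seed,
    )
    return sumstats, geno, cohort, truth
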