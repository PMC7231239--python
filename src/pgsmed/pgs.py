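"""Clumping + thresholding polygenic scores.

QC (strand-ambiguous removal), discovery/target harmonization, greedy
p-value-ordered LD clumping in a +/-250 kb window, and the weighted
effect-allele sum, with in-sample standardization of the score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import GenotypeMatrix, validate_sumstats

logger = logging.getLogger("pgsmed")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def remove_strand_ambiguous(sumstats: pd.DataFrame) -> pd.DataFrame:
    """Drop variants whose allele pair is self-complementary (A/T or C/G);
    such SNPs cannot be oriented across strand conventions."""
    a1 = sumstats["A1"].str.upper()
    a2 = sumstats["A2"].str.upper()
    ambiguous = a2 == a1.map(_COMPLEMENT)
    n = int(ambiguous.sum())
    if n:
        logger.info("removed %d strand-ambiguous variants of %d", n, len(sumstats))
    out = sumstats.loc[~ambiguous].reset_index(drop=True)
    if out.empty:
        logger.warning("no variants left after strand-ambiguity filter")
    return out


@dataclass
class HarmonizedPanel:
    """Variants shared by discovery and target, with dosage orientation.

    ``table`` columns: SNP, CHR, BP, BETA, P, EAF (discovery, may be NaN),
    ``flipped`` (effect allele is the target REF, so the effect-allele dosage
    is 2 - ALT dosage) and ``geno_index`` (column in the genotype matrix).
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    def at_threshold(self, p_threshold: float) -> pd.DataFrame:
        return self.table.loc[self.table["P"] <= p_threshold]

    def subset(self, snp_ids) -> "HarmonizedPanel":
        keep = self.table["SNP"].isin(set(snp_ids))
        return HarmonizedPanel(self.table.loc[keep].reset_index(drop=True))


def harmonize(sumstats: pd.DataFrame, geno: GenotypeMatrix) -> HarmonizedPanel:
    """Match variants by id and orient effect alleles against target REF/ALT.

    Effect allele equal to ALT keeps the dosage as-is; equal to REF flips it
    (beta applied to ``2 - dosage``); any other allele pair is dropped.
    Assumes strand-ambiguous variants were already removed.
    """
    ss = sumstats.set_index("SNP")
    tv = geno.variants
    shared = tv["SNP"].isin(ss.index).to_numpy()
    rows = []
    n_mismatch = 0
    for j in np.flatnonzero(shared):
        v = tv.iloc[j]
        rec = ss.loc[v.SNP]
        a1, a2 = rec["A1"].upper(), rec["A2"].upper()
        ref, alt = v.REF, v.ALT
        if a1 == alt and a2 == ref:
            flipped = False
        elif a1 == ref and a2 == alt:
            flipped = True
        else:
            n_mismatch += 1
            continue
        rows.append(
            {
                "SNP": v.SNP,
                "CHR": v.CHR,
                "BP": int(v.BP),
                "BETA": float(rec["BETA"]),
                "P": float(rec["P"]),
                "EAF": float(rec["EAF"]) if "EAF" in rec else np.nan,
                "flipped": flipped,
                "geno_index": int(j),
            }
        )
    if n_mismatch:
        logger.info("harmonize: dropped %d allele-mismatched variants", n_mismatch)
    if not rows:
        raise ValueError("no variants shared between discovery and target")
    logger.info("harmonize: %d variants present in both cohorts", len(rows))
    return HarmonizedPanel(pd.DataFrame(rows))


def estimate_ld(geno: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation of dosages at two variant columns over
    pairwise-complete individuals; monomorphic variants give r^2 = 0."""
    x, y = geno.dosage[:, i], geno.dosage[:, j]
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        logger.warning("estimate_ld: monomorphic or empty pair (%d, %d)", i, j)
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _r2_against(dosage: np.ndarray, j: int, cand: np.ndarray) -> np.ndarray:
    """Vectorised pairwise-complete r^2 of column ``j`` against ``cand``."""
    x = dosage[:, j]
    Y = dosage[:, cand]
    ok = ~np.isnan(x)[:, None] & ~np.isnan(Y)
    n = ok.sum(axis=0).astype(float)
    xs = np.where(ok, x[:, None], 0.0)
    ys = np.where(ok, Y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = xs.sum(axis=0) / n
        my = ys.sum(axis=0) / n
        sxy = np.einsum("ij,ij->j", xs, ys) / n - mx * my
        sxx = np.einsum("ij,ij->j", xs, xs) / n - mx * mx
        syy = np.einsum("ij,ij->j", ys, ys) / n - my * my
        r2 = (sxy * sxy) / (sxx * syy)
    r2[~np.isfinite(r2)] = 0.0  # monomorphic -> treated as independent
    return r2


@dataclass
class ClumpResult:
    """Greedy clumping output: retained index variants (selection order) and
    the pruned variants attributed to each index."""

    index_snps: list[str]
    pruned: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return len(self.index_snps)


def clump(
    panel: HarmonizedPanel,
    geno: GenotypeMatrix,
    window_kb: float = 250.0,
    r2_threshold: float = 0.1,
) -> ClumpResult:
    """Greedy p-value-ordered clumping.

    Repeatedly take the unpruned variant with the smallest p (ties: smaller
    position, then lexicographic id) as an index, then prune every unpruned
    variant on the same chromosome within +/- ``window_kb`` kb (inclusive)
    whose r^2 with the index exceeds ``r2_threshold``.
    """
    t = panel.table
    order = np.lexsort(
        (t["SNP"].to_numpy(), t["BP"].to_numpy(), t["P"].to_numpy())
    )
    bp = t["BP"].to_numpy()
    chrom = t["CHR"].to_numpy()
    gidx = t["geno_index"].to_numpy()
    snp = t["SNP"].to_numpy()
    window = window_kb * 1000.0
    state = np.zeros(len(t), dtype=np.int8)  # 0 free, 1 index, 2 pruned
    index_snps: list[str] = []
    pruned: dict[str, list[str]] = {}
    for k in order:
        if state[k] != 0:
            continue
        state[k] = 1
        index_snps.append(snp[k])
        near = np.flatnonzero(
            (state == 0) & (chrom == chrom[k]) & (np.abs(bp - bp[k]) <= window)
        )
        if near.size:
            r2 = _r2_against(geno.dosage, gidx[k], gidx[near])
            hit = near[r2 > r2_threshold]
            state[hit] = 2
            pruned[snp[k]] = [snp[h] for h in hit]
        else:
            pruned[snp[k]] = []
    return ClumpResult(index_snps, pruned)


@dataclass
class PgsVector:
    """Per-individual polygenic score (raw and in-sample standardized)."""

    raw: np.ndarray
    std: np.ndarray
    n_snps: int


def score(
    panel: HarmonizedPanel, geno: GenotypeMatrix, p_threshold: float = 1.0
) -> PgsVector:
    """Weighted effect-allele sum over panel variants with ``P <= Pt``.

    Missing dosages are mean-imputed with twice the target-sample
    effect-allele frequency.  The standardized score has mean 0 and SD 1
    over the sample; with no passing variants the score is all-zero.
    """
    sub = panel.at_threshold(p_threshold)
    n = geno.n_samples
    if sub.empty:
        logger.warning("score: no variants pass Pt=%g", p_threshold)
        z = np.zeros(n)
        return PgsVector(z, z.copy(), 0)
    gidx = sub["geno_index"].to_numpy()
    d = geno.dosage[:, gidx]
    flipped = sub["flipped"].to_numpy()
    eff = np.where(flipped, 2.0 - d, d)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(eff, axis=0) / 2.0
    freq = np.nan_to_num(freq, nan=0.0)
    eff = np.where(np.isnan(eff), 2.0 * freq, eff)
    raw = eff @ sub["BETA"].to_numpy()
    sd = raw.std()
    std = (raw - raw.mean()) / sd if sd > 0 else np.zeros(n)
    if sd == 0:
        logger.warning("score: zero variance at Pt=%g", p_threshold)
    return PgsVector(raw, std, len(sub))


class PolygenicScorer(BaseEstimator):
    """Clumping+thresholding PGS as a transformer.

    ``fit(sumstats, genotypes)`` runs QC, harmonization and clumping and
    stores the independent panel; ``transform(p_threshold=...)`` returns the
    standardized score for the fitted target sample.
    """

    def __init__(self, window_kb: float = 250.0, r2_threshold: float = 0.1,
                 p_threshold: float = 1.0, drop_ambiguous: bool = True):
        self.window_kb = window_kb
        self.r2_threshold = r2_threshold
        self.p_threshold = p_threshold
        self.drop_ambiguous = drop_ambiguous

    def fit(self, sumstats: pd.DataFrame, genotypes: GenotypeMatrix):
        ss = validate_sumstats(sumstats)
        if self.drop_ambiguous:
            ss = remove_strand_ambiguous(ss)
        panel = harmonize(ss, genotypes)
        self.clump_result_ = clump(
            panel, genotypes, self.window_kb, self.r2_threshold
        )
        self.panel_ = panel.subset(self.clump_result_.index_snps)
        self.genotypes_ = genotypes
        self.n_variants_harmonized_ = len(panel)
        return self

    def transform(self, genotypes: GenotypeMatrix | None = None,
                  p_threshold: float | None = None) -> PgsVector:
        if not hasattr(self, "panel_"):
            raise RuntimeError("PolygenicScorer is not fitted")
        geno = genotypes if genotypes is not None else self.genotypes_
        pt = p_threshold if p_threshold is not None else self.p_threshold
        return score(self.panel_, geno, pt)

    def fit_transform(self, sumstats, genotypes, **kw):
        return self.fit(sumstats, genotypes).transform(**kw)
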