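"""Readers, writers and validation for the pipeline's file formats.

All format dialects are decided here: GIANT-style tab-delimited summary
statistics (``SNP CHR BP A1 A2 EAF BETA SE P``), a VCF v4.2 subset (GT and
optional DS) for target genotypes, plain dosage matrices, and tab-delimited
phenotype tables with ``NA`` for missing.  Positions are 1-based throughout
(VCF convention).  Readers never reorder records; rows violating invariants
are dropped with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("pgsmed")

SUMSTAT_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "EAF", "BETA", "SE", "P"]
VALID_ALLELES = frozenset("ACGT")

#: phenotype-table columns (long names per outcome, ``NA`` for missing)
BINARY_OUTCOMES = [
    "fasting14", "fasting16", "fasting18",
    "binge14", "binge16", "binge18",
    "purging16", "purging18",
]
CONTINUOUS_OUTCOMES = [
    "thin_ideal14", "body_dissat14", "restrained14", "emotional14", "external14",
]
COVARIATES = ["sex", "pc1", "pc2", "pc3", "pc4"]


class FormatError(ValueError):
    """Malformed input file (missing column, inconsistent records)."""


@dataclass
class GenotypeMatrix:
    """Individuals x variants effect-agnostic ALT-allele dosages.

    ``dosage`` holds values in [0, 2] with ``NaN`` for missing calls.
    ``variants`` carries SNP, CHR, BP, REF, ALT in input order; positions
    must be non-decreasing within a chromosome.
    """

    dosage: np.ndarray
    variants: pd.DataFrame
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise FormatError("dosage must be 2-D (individuals x variants)")
        if self.dosage.shape[1] != len(self.variants):
            raise FormatError("variant metadata does not match dosage columns")
        if self.samples and len(self.samples) != self.dosage.shape[0]:
            raise FormatError("sample ids do not match dosage rows")
        for _, grp in self.variants.groupby("CHR", sort=False):
            if not np.all(np.diff(grp["BP"].to_numpy()) >= 0):
                raise FormatError("positions must be non-decreasing within chromosome")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def alt_frequency(self) -> np.ndarray:
        """Per-variant ALT allele frequency over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def subset_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosage[:, index],
            self.variants.iloc[index].reset_index(drop=True),
            list(self.samples),
        )


def validate_sumstats(df: pd.DataFrame, drop_invalid: bool = True) -> pd.DataFrame:
    """Enforce the SummaryStats invariants; invalid rows dropped + logged."""
    for col in SUMSTAT_COLUMNS:
        if col not in df.columns and col != "EAF":  # EAF optional
            raise FormatError(f"summary statistics missing mandatory column {col!r}")
    df = df.copy()
    for col in ("BP", "EAF", "BETA", "SE", "P"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df["A1"] = df["A1"].astype(str).str.upper()
    df["A2"] = df["A2"].astype(str).str.upper()
    ok = (
        df["A1"].isin(VALID_ALLELES)
        & df["A2"].isin(VALID_ALLELES)
        & (df["A1"] != df["A2"])
        & df["BETA"].notna()
        & df["SE"].notna()
        & (df["SE"] > 0)
        & df["P"].notna()
        & (df["P"] > 0)  # boundary rule: p must lie in (0, 1]
        & (df["P"] <= 1)
        & df["BP"].notna()
    )
    ok &= ~df["SNP"].duplicated(keep="first")
    n_drop = int((~ok).sum())
    if n_drop and not drop_invalid:
        raise FormatError(f"{n_drop} invalid summary-statistic rows")
    if n_drop:
        logger.warning("sumstats: dropped %d invalid rows of %d", n_drop, len(df))
    return df.loc[ok].reset_index(drop=True)


def read_sumstats(path) -> pd.DataFrame:
    """Read tab-delimited GWAS summary statistics (header SNP CHR BP A1 A2
    EAF BETA SE P); rows with unparsable numerics, identical alleles or
    out-of-range p are dropped with a logged count."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str})
    return validate_sumstats(df)


def write_sumstats(df: pd.DataFrame, path) -> None:
    cols = [c for c in SUMSTAT_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols, na_rep="NA")


def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Read target genotypes from VCF (GT, optional DS) or a dosage matrix.

    GT is converted to ALT dosage in {0,1,2}; ``./.`` becomes missing; a DS
    field, when present, takes precedence over GT.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "matrix":
        return _read_dosage_matrix(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    dosages = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1  # SNP-only analysis: drop indels/multi-allelics
            continue
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
            d = np.where((d < 0) | (d > 2), np.nan, d)
        else:
            gt = rec.genotype.array()  # (n, ploidy+1); -1 = missing allele
            alleles = gt[:, :2]
            d = np.where(
                np.any(alleles < 0, axis=1), np.nan, np.sum(alleles > 0, axis=1)
            ).astype(float)
        if d.shape[0] != len(samples):
            raise FormatError("sample count mismatch between header and records")
        dosages.append(d)
        rows.append(
            {
                "SNP": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "CHR": str(rec.CHROM),
                "BP": int(rec.POS),
                "REF": rec.REF.upper(),
                "ALT": rec.ALT[0].upper(),
            }
        )
    if n_skipped:
        logger.warning("vcf: dropped %d non-SNP/multi-allelic records", n_skipped)
    if not rows:
        raise FormatError("no usable variant records in VCF")
    return GenotypeMatrix(
        np.asarray(dosages, dtype=float).T, pd.DataFrame(rows), samples
    )


def _read_dosage_matrix(path) -> GenotypeMatrix:
    """Dosage matrix: columns SNP CHR BP REF ALT then one column per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str}, na_values="NA")
    meta_cols = ["SNP", "CHR", "BP", "REF", "ALT"]
    for col in meta_cols:
        if col not in df.columns:
            raise FormatError(f"dosage matrix missing column {col!r}")
    samples = [c for c in df.columns if c not in meta_cols]
    dosage = df[samples].to_numpy(dtype=float).T
    if np.nanmax(dosage, initial=0) > 2 or np.nanmin(dosage, initial=0) < 0:
        raise FormatError("dosages must lie in [0, 2]")
    return GenotypeMatrix(dosage, df[meta_cols].reset_index(drop=True), samples)


def write_vcf(geno: GenotypeMatrix, path, write_ds: bool = False) -> None:
    """Write a minimal VCF v4.2 (GT from rounded dosage; DS optional)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if write_ds:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        fmt = "GT:DS" if write_ds else "GT"
        for j in range(geno.n_variants):
            v = geno.variants.iloc[j]
            cells = []
            for d in geno.dosage[:, j]:
                if np.isnan(d):
                    cell = "./." + (":." if write_ds else "")
                else:
                    gt = gt_codes[int(round(d))]
                    cell = f"{gt}:{d:g}" if write_ds else gt
                cells.append(cell)
            fh.write(
                f"{v.CHR}\t{v.BP}\t{v.SNP}\t{v.REF}\t{v.ALT}\t.\t.\t.\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )


def write_dosage_matrix(geno: GenotypeMatrix, path) -> None:
    df = geno.variants.copy()
    for i, s in enumerate(geno.samples):
        df[s] = geno.dosage[i]
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_phenotypes(path) -> pd.DataFrame:
    """Tab-delimited phenotype/covariate table; 'NA' marks missing."""
    df = pd.read_csv(path, sep="\t", na_values="NA", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError("phenotype table missing mandatory column 'sample_id'")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.8g")


def align_samples(
    geno: GenotypeMatrix, cohort: pd.DataFrame
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Intersect genotype and phenotype samples; order fixed by genotypes."""
    cohort_ids = set(cohort["sample_id"])
    keep = [i for i, s in enumerate(geno.samples) if s in cohort_ids]
    if not keep:
        raise ValueError("no samples shared between genotypes and cohort table")
    n_drop_g = geno.n_samples - len(keep)
    samples = [geno.samples[i] for i in keep]
    n_drop_c = len(cohort) - len(samples)
    if n_drop_g or n_drop_c:
        logger.info(
            "align_samples: dropped %d genotype-only and %d cohort-only ids",
            n_drop_g, n_drop_c,
        )
    aligned = GenotypeMatrix(geno.dosage[keep], geno.variants, samples)
    tab = cohort.set_index("sample_id").loc[samples].reset_index()
    return aligned, tab


def write_run_metadata(meta: dict, path) -> None:
    """YAML sidecar recording seed, thresholds and settings of a run."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
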