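"""End-to-end orchestration: simulate/load -> score -> scan -> associate ->
glmm -> mediate, with every intermediate written to a run directory and a
YAML metadata sidecar.  A fixed top-level seed makes reruns bit-identical;
per-stage substreams are derived from it with fixed labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .association import (
    association_table,
    fdr_across_phenotypes,
    fit_association,
)
from .glmm import build_long_table, fit_glmm_interaction
from .mediation import CausalMediation, mediation_report
from .pgs import PolygenicScorer
from .simulate import SimulationConfig, simulate_study
from .threshold import ThresholdScan, default_grid

logger = logging.getLogger("pgsmed")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative run description.

    Exactly one of ``simulation`` or the three input paths must be given.
    """

    simulation: SimulationConfig | None = None
    sumstats_path: str | None = None
    genotypes_path: str | None = None
    genotypes_format: str = "vcf"
    phenotypes_path: str | None = None
    outcomes: list[str] = field(
        default_factory=lambda: ["fasting14", "body_dissat14"]
    )
    glmm_behaviour: str | None = "fasting"
    mediate: bool = True
    grid: list[float] | None = None
    n_perm: int = 0
    n_boot: int = 1000
    seed: int = 0
    out_dir: str = "pgsmed_run"

    def validate(self) -> "RunConfig":
        has_paths = any(
            p is not None
            for p in (self.sumstats_path, self.genotypes_path, self.phenotypes_path)
        )
        if has_paths == (self.simulation is not None):
            raise ValueError(
                "exactly one of (input paths, simulation config) must be set"
            )
        if has_paths and not all(
            (self.sumstats_path, self.genotypes_path, self.phenotypes_path)
        ):
            raise ValueError("all three input paths are required")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            if "prevalence_targets" in sim:
                sim["prevalence_targets"] = dict(sim["prevalence_targets"])
            if "maf_range" in sim:
                sim["maf_range"] = tuple(sim["maf_range"])
            cfg.simulation = SimulationConfig(**sim)
        return cfg.validate()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Any stage error aborts with the stage name; artifacts written by earlier
    stages are preserved.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "n_perm": config.n_perm, "n_boot": config.n_boot,
            "stages": []}

    stage = "inputs"
    try:
        if config.simulation is not None:
            sim = config.simulation
            sumstats, geno, cohort, _truth = simulate_study(sim)
            io.write_sumstats(sumstats, out / "sumstats.tsv")
            io.write_vcf(geno, out / "genotypes.vcf")
            io.write_phenotypes(cohort, out / "phenotypes.tsv")
            meta["simulation"] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(sim).items()
                if not isinstance(v, dict)
            }
        else:
            sumstats = io.read_sumstats(config.sumstats_path)
            geno = io.read_genotypes(
                config.genotypes_path, format=config.genotypes_format
            )
            cohort = io.read_phenotypes(config.phenotypes_path)
        # MAR can drop rows with no observed outcome; keep the intersection
        geno, cohort = io.align_samples(geno, cohort)
        meta["stages"].append(stage)

        stage = "score"
        scorer = PolygenicScorer()
        scorer.fit(sumstats, geno)
        pgs_full = scorer.transform(p_threshold=1.0)
        _write(
            pd.DataFrame(
                {
                    "sample_id": geno.samples,
                    "raw_score": pgs_full.raw,
                    "std_score": pgs_full.std,
                }
            ),
            out / "scores_pt1.tsv",
        )
        clump_rows = [
            {"index_snp": k, "pruned": ",".join(v) or "."}
            for k, v in scorer.clump_result_.pruned.items()
        ]
        _write(pd.DataFrame(clump_rows), out / "clump_report.tsv")
        meta["n_variants_harmonized"] = scorer.n_variants_harmonized_
        meta["n_index_snps"] = scorer.clump_result_.n_retained
        meta["stages"].append(stage)

        stage = "scan"
        grid = np.asarray(config.grid, float) if config.grid else default_grid()
        cohort_idx = cohort.set_index("sample_id")
        covariates = cohort_idx[["sex", "pc1", "pc2", "pc3", "pc4"]].to_numpy(float)
        best_scores: dict[str, np.ndarray] = {}
        scan_summaries = []
        for outcome in config.outcomes:
            est = ThresholdScan(grid=grid, n_perm=config.n_perm, seed=config.seed)
            est.fit(scorer.panel_, geno, cohort_idx[outcome].to_numpy(float),
                    covariates)
            res = est.results_
            _write(res.table, out / f"scan_{outcome}.tsv")
            best_scores[outcome] = scorer.transform(
                p_threshold=res.best_threshold
            ).std
            scan_summaries.append(
                {
                    "outcome": outcome,
                    "best_threshold": res.best_threshold,
                    "n_snps": res.best_n_snps,
                    "r2_observed": res.best_r2_observed,
                    "r2_liability": res.best_r2_liability,
                    "empirical_p": res.empirical_p,
                }
            )
        _write(pd.DataFrame(scan_summaries), out / "scan_summary.tsv")
        meta["stages"].append(stage)

        stage = "associate"
        results = []
        cohort_aligned = cohort_idx.reset_index()
        for outcome in config.outcomes:
            results.append(
                fit_association(cohort_aligned, outcome, best_scores[outcome])
            )
        fdr_across_phenotypes(results)
        _write(association_table(results), out / "association.tsv")
        meta["stages"].append(stage)

        if config.glmm_behaviour:
            stage = "glmm"
            long = build_long_table(
                cohort_aligned, pgs_full.std, config.glmm_behaviour
            )
            if long["age"].nunique() >= 2:
                g = fit_glmm_interaction(long)
                tab = g.params.reset_index(names="term")
                tab["sigma2"] = g.sigma2
                _write(tab, out / f"glmm_{config.glmm_behaviour}.tsv")
                meta["glmm_interaction_p"] = float(g.interaction_p)
            meta["stages"].append(stage)

        if config.mediate:
            stage = "mediate"
            med_results = []
            for outcome in config.outcomes:
                df = cohort_aligned.copy()
                df["std_score"] = best_scores[outcome]
                est = CausalMediation(
                    outcome=outcome,
                    n_resamples=config.n_boot,
                    seed=config.seed,
                )
                med_results.append(est.fit(df).result_)
            _write(mediation_report(med_results), out / "mediation.tsv")
            meta["stages"].append(stage)
    except Exception as exc:
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc

    import pgsmed

    meta["version"] = getattr(pgsmed, "__version__", "unknown")
    meta["grid"] = "default" if config.grid is None else list(map(float, config.grid))
    meta["clump_window_kb"] = 250.0
    meta["clump_r2"] = 0.1
    io.write_run_metadata(meta, out / "run_metadata.yaml")
    return out
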