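import numpy as np
import pandas as pd
import pytest

from pgsmed.io import GenotypeMatrix
from pgsmed.pgs import HarmonizedPanel
from pgsmed.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """One small synthetic study shared by read-only tests."""
    cfg = SimulationConfig(
        n_individuals=1200, n_variants=300, n_causal=50, ld_block_size=25,
        seed=11,
    )
    sumstats, geno, cohort, truth = simulate_study(cfg)
    return cfg, sumstats, geno, cohort, truth


def make_genotypes(rng, n, m, spacing=5000, maf_low=0.1, maf_high=0.5,
                   positions=None):
    """Independent-variant genotype matrix for constructed fixtures."""
    maf = rng.uniform(maf_low, maf_high, size=m)
    dosage = rng.binomial(2, maf, size=(n, m)).astype(float)
    pairs = [("A", "G"), ("C", "T"), ("T", "G"), ("G", "A")]
    variants = pd.DataFrame(
        {
            "SNP": [f"rs{j}" for j in range(m)],
            "CHR": "1",
            "BP": positions if positions is not None
            else 1 + spacing * np.arange(m),
            "REF": [pairs[j % 4][0] for j in range(m)],
            "ALT": [pairs[j % 4][1] for j in range(m)],
        }
    )
    return GenotypeMatrix(dosage, variants, [f"S{i}" for i in range(n)])


def make_panel(geno, betas=None, pvals=None, flipped=None):
    """HarmonizedPanel over all variants of a genotype fixture."""
    m = geno.n_variants
    rngdefault = np.random.default_rng(0)
    t = pd.DataFrame(
        {
            "SNP": geno.variants["SNP"],
            "CHR": geno.variants["CHR"],
            "BP": geno.variants["BP"],
            "BETA": betas if betas is not None else rngdefault.normal(size=m),
            "P": pvals if pvals is not None else rngdefault.uniform(size=m),
            "EAF": geno.alt_frequency(),
            "flipped": flipped if flipped is not None else np.zeros(m, bool),
            "geno_index": np.arange(m),
        }
    )
    return HarmonizedPanel(t)
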