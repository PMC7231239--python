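"""QC, harmonization, LD, clumping (vs a naive reference) and scoring."""

import numpy as np
import pandas as pd
import pytest

from pgsmed.io import GenotypeMatrix
from pgsmed.pgs import (
    HarmonizedPanel,
    PolygenicScorer,
    clump,
    estimate_ld,
    harmonize,
    remove_strand_ambiguous,
    score,
)

from conftest import make_genotypes, make_panel


def _ss(rows):
    return pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "A1", "A2",
                                       "EAF", "BETA", "SE", "P"])


class TestStrandAmbiguous:
    @pytest.mark.parametrize(
        "a1,a2,kept",
        [("A", "T", False), ("T", "A", False), ("C", "G", False),
         ("G", "C", False), ("A", "G", True), ("C", "T", True),
         ("G", "T", True), ("A", "C", True)],
    )
    def test_complement_pairs_removed(self, a1, a2, kept):
        ss = _ss([("rs1", "1", 100, a1, a2, 0.2, 0.1, 0.01, 0.5)])
        out = remove_strand_ambiguous(ss)
        assert (len(out) == 1) is kept

    def test_enumerated_example(self):
        pairs = [("A", "G"), ("C", "T"), ("A", "T"), ("C", "G"),
                 ("G", "T"), ("A", "C")]
        ss = _ss([(f"rs{i}", "1", 100 * (i + 1), a1, a2, 0.2, 0.1, 0.01, 0.5)
                  for i, (a1, a2) in enumerate(pairs)])
        assert len(remove_strand_ambiguous(ss)) == 4


class TestHarmonize:
    @pytest.fixture
    def geno(self):
        variants = pd.DataFrame(
            {"SNP": ["rs1", "rs2", "rs3"], "CHR": "1",
             "BP": [100, 5100, 10100],
             "REF": ["A", "C", "T"], "ALT": ["G", "T", "G"]}
        )
        rng = np.random.default_rng(5)
        return GenotypeMatrix(rng.binomial(2, 0.4, (30, 3)).astype(float),
                              variants, [f"S{i}" for i in range(30)])

    def test_orientation(self, geno):
        ss = _ss([
            ("rs1", "1", 100, "G", "A", 0.3, 0.2, 0.01, 0.1),   # A1 == ALT
            ("rs2", "1", 5100, "C", "T", 0.3, 0.4, 0.01, 0.1),  # A1 == REF
            ("rs3", "1", 10100, "A", "C", 0.3, 0.1, 0.01, 0.1),  # mismatch
        ])
        panel = harmonize(ss, geno)
        t = panel.table.set_index("SNP")
        assert not t.loc["rs1", "flipped"]
        assert t.loc["rs2", "flipped"]
        assert "rs3" not in t.index

    def test_flipped_score_matches_manual_recoding(self, geno):
        ss = _ss([("rs2", "1", 5100, "C", "T", 0.3, 0.4, 0.01, 0.1)])
        panel = harmonize(ss, geno)
        got = score(panel, geno, 1.0).raw
        manual = 0.4 * (2.0 - geno.dosage[:, 1])
        np.testing.assert_allclose(got, manual, atol=1e-12)

    def test_no_shared_variants_error(self, geno):
        ss = _ss([("rs99", "1", 900, "A", "G", 0.3, 0.2, 0.01, 0.1)])
        with pytest.raises(ValueError):
            harmonize(ss, geno)


class TestEstimateLd:
    def test_self_and_duplicate(self):
        rng = np.random.default_rng(0)
        g = make_genotypes(rng, 200, 2)
        g.dosage[:, 1] = g.dosage[:, 0]
        assert estimate_ld(g, 0, 0) == pytest.approx(1.0)
        assert estimate_ld(g, 0, 1) == pytest.approx(1.0)

    def test_independent_variants_near_zero(self):
        rng = np.random.default_rng(1)
        g = make_genotypes(rng, 10_000, 2)
        assert estimate_ld(g, 0, 1) < 0.01

    def test_monomorphic_defined_zero(self):
        rng = np.random.default_rng(2)
        g = make_genotypes(rng, 50, 2)
        g.dosage[:, 1] = 1.0
        assert estimate_ld(g, 0, 1) == 0.0


def brute_force_clump(bp, pvals, snp, r2mat, window_bp, r2_thr):
    """Naive reference: repeated scan for the smallest-p survivor, pruning
    neighbours one comparison at a time."""
    remaining = set(range(len(bp)))
    retained = []
    while remaining:
        best = min(remaining, key=lambda i: (pvals[i], bp[i], snp[i]))
        retained.append(best)
        remaining.discard(best)
        for other in sorted(remaining):
            if abs(bp[other] - bp[best]) <= window_bp:
                if r2mat[best][other] > r2_thr:
                    remaining.discard(other)
    return retained


def _pairwise_r2(dosage):
    m = dosage.shape[1]
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            x, y = dosage[:, i], dosage[:, j]
            if x.std() == 0 or y.std() == 0:
                out[i, j] = 0.0
            else:
                out[i, j] = np.corrcoef(x, y)[0, 1] ** 2
    return out


class TestClump:
    def test_single_variant_retained(self):
        rng = np.random.default_rng(3)
        g = make_genotypes(rng, 50, 1)
        panel = make_panel(g, pvals=[0.01])
        res = clump(panel, g)
        assert res.index_snps == ["rs0"]

    def test_smaller_p_wins_within_window(self):
        rng = np.random.default_rng(4)
        g = make_genotypes(rng, 400, 2, positions=[100, 10_100])
        g.dosage[:, 1] = np.clip(
            g.dosage[:, 0] + (rng.random(400) < 0.3), 0, 2
        )  # correlated pair, r2 well above 0.1
        panel = make_panel(g, pvals=[1e-8, 1e-4])
        res = clump(panel, g)
        assert res.index_snps == ["rs0"]
        assert res.pruned["rs0"] == ["rs1"]

    def test_five_variant_toy_matches_reference(self):
        rng = np.random.default_rng(5)
        positions = [1, 100_001, 200_001, 400_001, 410_001]
        g = make_genotypes(rng, 600, 5, positions=positions)
        # make 0-1 and 3-4 correlated
        g.dosage[:, 1] = np.clip(g.dosage[:, 0] + (rng.random(600) < 0.2), 0, 2)
        g.dosage[:, 4] = np.clip(g.dosage[:, 3] + (rng.random(600) < 0.2), 0, 2)
        pvals = [1e-3, 1e-6, 0.5, 1e-5, 1e-7]
        panel = make_panel(g, pvals=pvals)
        res = clump(panel, g)
        ref = brute_force_clump(
            positions, pvals, [f"rs{j}" for j in range(5)],
            _pairwise_r2(g.dosage), 250_000, 0.1,
        )
        assert res.index_snps == [f"rs{j}" for j in ref]

    def test_order_invariance(self):
        rng = np.random.default_rng(6)
        g = make_genotypes(rng, 300, 8, spacing=60_000)
        pvals = rng.uniform(size=8)
        panel = make_panel(g, pvals=pvals)
        res1 = clump(panel, g)
        perm = rng.permutation(8)
        shuffled = HarmonizedPanel(
            panel.table.iloc[perm].reset_index(drop=True)
        )
        res2 = clump(shuffled, g)
        assert res1.index_snps == res2.index_snps

    def test_ties_broken_by_position_then_id(self):
        rng = np.random.default_rng(7)
        g = make_genotypes(rng, 100, 2, positions=[100, 500_000])
        panel = make_panel(g, pvals=[0.5, 0.5])
        res = clump(panel, g)
        assert res.index_snps[0] == "rs0"  # smaller position wins the tie


class TestScore:
    def test_weighted_sum_arithmetic(self):
        rng = np.random.default_rng(8)
        g = make_genotypes(rng, 1, 3)
        g.dosage[0] = [2.0, 0.0, 1.0]
        panel = make_panel(g, betas=[0.1, -0.2, 0.3], pvals=[0.1] * 3)
        assert score(panel, g, 1.0).raw[0] == pytest.approx(0.5)

    def test_zero_betas_zero_score(self):
        rng = np.random.default_rng(9)
        g = make_genotypes(rng, 20, 4)
        panel = make_panel(g, betas=np.zeros(4))
        np.testing.assert_array_equal(score(panel, g, 1.0).raw, np.zeros(20))

    def test_missing_dosage_imputed_with_sample_eaf(self):
        rng = np.random.default_rng(10)
        g = make_genotypes(rng, 5, 1)
        g.dosage[:, 0] = [1.0, 1.0, 0.0, 0.0, np.nan]  # observed EAF = 0.25
        panel = make_panel(g, betas=[0.8], pvals=[0.01])
        raw = score(panel, g, 1.0).raw
        assert raw[4] == pytest.approx(0.8 * 2 * 0.25)  # beta * 0.5

    def test_threshold_filters_and_empty_result(self):
        rng = np.random.default_rng(11)
        g = make_genotypes(rng, 30, 3)
        panel = make_panel(g, betas=[0.1, 0.2, 0.3], pvals=[1e-8, 1e-4, 0.5])
        assert score(panel, g, 1e-6).n_snps == 1
        empty = score(panel, g, 1e-12)
        assert empty.n_snps == 0
        np.testing.assert_array_equal(empty.raw, np.zeros(30))

    def test_standardization_contract(self, small_study):
        _, sumstats, geno, _, _ = small_study
        v = PolygenicScorer().fit(sumstats, geno).transform(p_threshold=1.0)
        assert abs(v.std.mean()) < 1e-8
        assert abs(v.std.std() - 1) < 1e-8

    def test_score_linearity(self):
        rng = np.random.default_rng(12)
        g = make_genotypes(rng, 40, 5)
        b1 = rng.normal(size=5)
        b2 = rng.normal(size=5)
        p = rng.uniform(size=5)
        s1 = score(make_panel(g, betas=b1, pvals=p), g, 1.0).raw
        s2 = score(make_panel(g, betas=b2, pvals=p), g, 1.0).raw
        s12 = score(make_panel(g, betas=b1 + b2, pvals=p), g, 1.0).raw
        np.testing.assert_allclose(s12, s1 + s2, atol=1e-10)

    def test_n_snps_monotone_in_threshold(self, small_study):
        _, sumstats, geno, _, _ = small_study
        scorer = PolygenicScorer().fit(sumstats, geno)
        counts = [scorer.transform(p_threshold=pt).n_snps
                  for pt in (1e-8, 1e-5, 1e-3, 0.05, 0.5, 1.0)]
        assert counts == sorted(counts)


def test_scorer_is_sklearn_compatible():
    est = PolygenicScorer(window_kb=100.0)
    params = est.get_params()
    assert params["window_kb"] == 100.0
    est.set_params(r2_threshold=0.2)
    assert est.r2_threshold == 0.2
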