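"""Generator contracts: LD structure, sumstats noise, calibration, MAR."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from pgsmed.simulate import (
    ORDINAL_LEVELS,
    SimulationConfig,
    apply_mar_missingness,
    dichotomize_frequency,
    draw_true_model,
    simulate_cohort,
    simulate_discovery_sumstats,
    simulate_genotypes,
    simulate_study,
)


class TestGenotypes:
    def test_dosage_range_and_shape(self):
        cfg = SimulationConfig(n_individuals=4, n_variants=3, n_causal=1,
                               within_block_r=0.0, seed=1)
        g = simulate_genotypes(cfg)
        assert g.dosage.shape == (4, 3)
        assert set(np.unique(g.dosage)) <= {0.0, 1.0, 2.0}

    def test_positions_fixed_5kb_single_chromosome(self):
        g = simulate_genotypes(SimulationConfig(n_individuals=5, n_variants=60,
                                                n_causal=5, seed=2))
        bp = g.variants["BP"].to_numpy()
        assert set(np.diff(bp)) == {5000}
        assert set(g.variants["CHR"]) == {"1"}

    def test_block_ld_exceeds_cross_block(self):
        cfg = SimulationConfig(n_individuals=2000, n_variants=60, n_causal=5,
                               ld_block_size=10, within_block_r=0.9, seed=3)
        g = simulate_genotypes(cfg)
        r2 = np.corrcoef(g.dosage.T) ** 2
        block = np.arange(60) // 10
        same = block[:, None] == block[None, :]
        off = ~np.eye(60, dtype=bool)
        within = r2[same & off].mean()
        cross = r2[~same].mean()
        assert within - cross > 0.3

    def test_determinism(self):
        cfg = SimulationConfig(n_individuals=50, n_variants=40, n_causal=5, seed=9)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.dosage, b.dosage)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_individuals=0).validate()
        with pytest.raises(ValueError):
            SimulationConfig(n_causal=10, n_variants=5).validate()
        with pytest.raises(ValueError):
            SimulationConfig(within_block_r=1.0).validate()


class TestDiscoverySumstats:
    def test_infinite_discovery_recovers_causal_betas(self):
        # no LD: marginal effects equal causal effects; noise ~ 1/sqrt(N)
        cfg = SimulationConfig(n_individuals=3000, n_variants=50, n_causal=20,
                               within_block_r=0.0, seed=4, n_discovery=10**9)
        g = simulate_genotypes(cfg)
        tm = draw_true_model(g, cfg)
        ss = simulate_discovery_sumstats(g, tm, 10**9, seed=4)
        # empirical-correlation smear at n=3000 adds ~|beta|/sqrt(n) leakage;
        # compare at causal sites where it is negligible
        causal = np.flatnonzero(tm.causal_betas)
        assert np.max(np.abs(ss["BETA"].to_numpy()[causal]
                             - tm.causal_betas[causal])) < 1e-3

    def test_null_pvalues_uniform(self):
        cfg = SimulationConfig(n_individuals=300, n_variants=10_000, n_causal=1,
                               h2_score=0.0, within_block_r=0.0,
                               ld_block_size=100, seed=5)
        g = simulate_genotypes(cfg)
        tm = draw_true_model(g, cfg)  # h2=0: all betas exactly 0
        ss = simulate_discovery_sumstats(g, tm, 100_000, seed=5)
        ks = stats.kstest(ss["P"], "uniform").statistic
        assert ks < 0.02

    def test_exact_ambiguous_fraction(self):
        cfg = SimulationConfig(n_individuals=40, n_variants=100, n_causal=5, seed=6)
        g = simulate_genotypes(cfg)
        tm = draw_true_model(g, cfg)
        ss = simulate_discovery_sumstats(g, tm, 10_000, seed=6,
                                         ambiguous_fraction=0.2)
        pair = ss["A1"] + ss["A2"]
        assert pair.isin(["AT", "TA", "CG", "GC"]).sum() == 20

    def test_nonpositive_discovery_n_rejected(self):
        cfg = SimulationConfig(n_individuals=20, n_variants=10, n_causal=2, seed=1)
        g = simulate_genotypes(cfg)
        tm = draw_true_model(g, cfg)
        with pytest.raises(ValueError):
            simulate_discovery_sumstats(g, tm, 0, seed=1)


@pytest.fixture(scope="module")
def big_cohort():
    cfg = SimulationConfig(n_individuals=10_000, n_variants=200, n_causal=40,
                           seed=21)
    g = simulate_genotypes(cfg)
    tm = draw_true_model(g, cfg)
    return cfg, g, tm, simulate_cohort(g, tm, cfg)


class TestCohort:
    def test_prevalence_calibration(self, big_cohort):
        cfg, _, _, cohort = big_cohort
        realized = cohort["fasting14"].mean()
        target = cfg.prevalence_targets["fasting14"]
        assert 0.8 * target <= realized <= 1.2 * target

    def test_zbmi_standardized_within_sex(self, big_cohort):
        _, _, _, cohort = big_cohort
        for _, grp in cohort.groupby("sex"):
            assert abs(grp["zbmi11"].mean()) < 0.05
            assert 0.95 <= grp["zbmi11"].std() <= 1.05

    def test_score_mediator_correlation_matches_path(self, big_cohort):
        cfg, _, tm, cohort = big_cohort
        r = np.corrcoef(cohort["true_score"], cohort["zbmi11"])[0, 1]
        expected = cfg.a_path / np.sqrt(cfg.a_path**2 + 1)
        assert abs(r - expected) < 0.03

    def test_binary_consistent_with_ordinal(self, big_cohort):
        _, _, _, cohort = big_cohort
        redich = dichotomize_frequency(cohort["fasting14_freq"])
        np.testing.assert_array_equal(redich, cohort["fasting14"].to_numpy())
        redich_b = dichotomize_frequency(cohort["binge14_freq"],
                                         cohort["binge14_loc"])
        np.testing.assert_array_equal(redich_b, cohort["binge14"].to_numpy())

    def test_null_paths_give_null_association(self):
        """With b=c'=0 the outcome slope on the true score should be null;
        the Wald CI covers zero in nearly all replicates."""
        covered = 0
        n_rep = 40
        for rep in range(n_rep):
            cfg = SimulationConfig(
                n_individuals=5000, n_variants=40, n_causal=10,
                b_path=0.0, c_prime=0.0, seed=1000 + rep,
                prevalence_targets={"fasting14": 0.065},
            )
            g = simulate_genotypes(cfg)
            tm = draw_true_model(g, cfg)
            cohort = simulate_cohort(g, tm, cfg)
            X = sm.add_constant(cohort[["true_score", "sex"]].to_numpy(float))
            fit = sm.Logit(cohort["fasting14"].to_numpy(float), X).fit(disp=0)
            lo = fit.params[1] - 1.96 * fit.bse[1]
            hi = fit.params[1] + 1.96 * fit.bse[1]
            covered += lo <= 0 <= hi
        assert covered >= int(0.93 * n_rep) - 1


class TestDichotomize:
    @pytest.mark.parametrize(
        "level,expected",
        [
            ("Never", 0),
            ("Less than once a month", 0),
            ("1-3 times a month", 1),
            ("Once a week", 1),
            ("2 or more times a week", 1),
        ],
    )
    def test_monthly_cut(self, level, expected):
        assert dichotomize_frequency(level) == expected

    def test_binge_requires_loss_of_control(self):
        assert dichotomize_frequency("Once a week", loss_of_control=False) == 0
        assert dichotomize_frequency("Once a week", loss_of_control=True) == 1

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_frequency("sometimes")

    def test_levels_are_the_five_response_options(self):
        assert len(ORDINAL_LEVELS) == 5


class TestMissingness:
    def test_realized_rate(self, big_cohort):
        _, _, _, cohort = big_cohort
        out = apply_mar_missingness(cohort, 0.3, 0.0, 0.0, seed=1,
                                    columns=["fasting14"])
        assert 0.28 <= out["miss_fasting14"].mean() <= 0.32

    def test_score_dependent_direction(self, big_cohort):
        _, _, _, cohort = big_cohort
        out = apply_mar_missingness(cohort, 0.3, 0.0, 0.5, seed=2,
                                    columns=["fasting14"])
        miss = out["miss_fasting14"] == 1
        assert out.loc[miss, "true_score"].mean() > out.loc[~miss, "true_score"].mean()

    def test_zero_rate_identity(self, big_cohort):
        _, _, _, cohort = big_cohort
        out = apply_mar_missingness(cohort, 0.0, seed=3)
        pd.testing.assert_frame_equal(out, cohort)

    def test_invalid_rate(self, big_cohort):
        _, _, _, cohort = big_cohort
        with pytest.raises(ValueError):
            apply_mar_missingness(cohort, 1.2, seed=1)

    def test_complete_case_unbiased_under_mar(self, big_cohort):
        """MAR driven by sex and score only: the complete-case logistic
        slope (adjusting for sex) matches the full-data slope closely."""
        _, _, _, cohort = big_cohort
        y = cohort["fasting14"].to_numpy(float)
        X = sm.add_constant(cohort[["true_score", "sex"]].to_numpy(float))
        full = sm.Logit(y, X).fit(disp=0)
        mar = apply_mar_missingness(cohort, 0.3, delta_sex=-0.5, delta_pgs=0.5,
                                    seed=4, columns=["fasting14"])
        keep = mar["fasting14"].notna().to_numpy()
        cc = sm.Logit(
            mar.loc[keep, "fasting14"].to_numpy(float),
            sm.add_constant(mar.loc[keep, ["true_score", "sex"]].to_numpy(float)),
        ).fit(disp=0)
        assert abs(cc.params[1] - full.params[1]) < 0.05


def test_full_study_determinism():
    cfg = SimulationConfig(n_individuals=300, n_variants=80, n_causal=10, seed=42)
    a = simulate_study(cfg)
    b = simulate_study(cfg)
    pd.testing.assert_frame_equal(a[0], b[0])
    np.testing.assert_array_equal(a[1].dosage, b[1].dosage)
    pd.testing.assert_frame_equal(a[2], b[2])
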