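"""Synthetic-herd generator: structure, determinism, variance composition."""

import numpy as np
import pandas as pd
import pytest

from shedeval.relatedness import a_matrix
from shedeval.simulate import (
    ConfigurationError,
    SimConfig,
    default_fescue_g0,
    default_maternal_g0,
    simulate_breeding_values,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_phenotypes_bivariate,
    simulate_selected_population,
    simulate_ww_bivariate,
)


class TestPedigree:
    def test_zero_generations_founders_only(self):
        cfg = SimConfig(n_founders=10, n_generations=0, seed=1)
        ped = simulate_pedigree(cfg)
        assert len(ped) == 10
        assert (ped.table["sire"] == "").all() and (ped.table["dam"] == "").all()

    def test_same_seed_identical_tables(self):
        cfg = SimConfig(n_founders=20, n_generations=2, progeny_per_dam=3, seed=7)
        p1 = simulate_pedigree(cfg)
        p2 = simulate_pedigree(SimConfig(n_founders=20, n_generations=2,
                                         progeny_per_dam=3, seed=7))
        pd.testing.assert_frame_equal(p1.table, p2.table)

    def test_offspring_counts_match_mating_loop_enumeration(self):
        # Oracle: dams per generation x progeny_per_dam, sexes alternating.
        cfg = SimConfig(n_founders=10, n_generations=2, progeny_per_dam=2, seed=3)
        ped = simulate_pedigree(cfg)
        gen = ped.table["generation"].value_counts().to_dict()
        assert gen[0] == 10
        assert gen[1] == 5 * 2  # 5 founder dams
        assert gen[2] == 5 * 2  # 10 gen-1 animals, half female

    def test_parents_precede_offspring(self):
        cfg = SimConfig(n_founders=12, n_generations=3, progeny_per_dam=2, seed=9)
        ped = simulate_pedigree(cfg)
        seen = set()
        for row in ped.table.itertuples():
            assert row.sire == "" or row.sire in seen
            assert row.dam == "" or row.dam in seen
            seen.add(row.animal)

    def test_impossible_structure_raises(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_founders=1)
        with pytest.raises(ConfigurationError):
            simulate_pedigree(SimConfig(n_founders=4, dam_fraction=1.0))


class TestGenotypes:
    def test_mendelian_consistency(self):
        cfg = SimConfig(n_founders=10, n_generations=2, progeny_per_dam=2,
                        genotyped_fraction=1.0, n_snps=50, seed=4)
        ped = simulate_pedigree(cfg)
        g = simulate_genotypes(ped, cfg)
        pos = {a: i for i, a in enumerate(g.animals)}
        for row in ped.table.itertuples():
            if not row.sire:
                continue
            c, s, d = (g.counts[pos[x]] for x in (row.animal, row.sire, row.dam))
            # both parents homozygous 0 -> child cannot carry the allele
            assert (c[(s == 0) & (d == 0)] == 0).all()
            assert (c[(s == 2) & (d == 2)] == 2).all()

    def test_hardy_weinberg_mean_at_half(self):
        cfg = SimConfig(n_founders=400, n_generations=0, genotyped_fraction=1.0,
                        n_snps=200, maf_range=(0.5, 0.5), seed=5)
        ped = simulate_pedigree(cfg)
        g = simulate_genotypes(ped, cfg)
        se = np.sqrt(0.5 / (400 * 200))  # binomial SE of the grand mean
        assert abs(g.counts.mean() - 1.0) < 3 * se

    def test_seed_reproducibility(self):
        cfg = SimConfig(n_founders=10, n_generations=1, n_snps=30, seed=6)
        ped = simulate_pedigree(cfg)
        g1 = simulate_genotypes(ped, cfg)
        g2 = simulate_genotypes(ped, cfg)
        np.testing.assert_array_equal(g1.counts, g2.counts)


class TestBreedingValues:
    def test_parent_offspring_regression_half(self):
        cfg = SimConfig(n_founders=300, n_generations=1, progeny_per_dam=3, seed=8)
        ped = simulate_pedigree(cfg)
        bv = simulate_breeding_values(ped, np.array([[1.0]]),
                                      np.random.default_rng(0))
        sire, dam = ped.parent_indices()
        child = sire >= 0
        mid = 0.5 * (bv[sire[child], 0] + bv[dam[child], 0])
        slope = np.polyfit(mid, bv[child, 0], 1)[0]
        assert abs(slope - 1.0) < 0.1  # slope on midparent = 1 <=> 0.5 per parent

    def test_variance_composition_within_mc_error(self):
        cfg = SimConfig(n_founders=2000, n_generations=0, seed=10)
        ped = simulate_pedigree(cfg)
        bv = simulate_breeding_values(ped, np.array([[0.38]]),
                                      np.random.default_rng(1))
        # founder BVs are iid N(0, 0.38): sampling SE of the variance
        se = 0.38 * np.sqrt(2 / (2000 - 1))
        assert abs(bv.var(ddof=1) - 0.38) < 3 * se

    def test_multitrait_covariance_recovered(self):
        g0 = default_maternal_g0()
        cfg = SimConfig(n_founders=3000, n_generations=0, seed=11)
        ped = simulate_pedigree(cfg)
        bv = simulate_breeding_values(ped, g0, np.random.default_rng(2))
        emp = np.cov(bv.T)
        np.testing.assert_allclose(emp, g0, rtol=0.12, atol=0.05 * np.sqrt(
            np.outer(np.diag(g0), np.diag(g0))).max())


class TestPhenotypes:
    def test_residual_only_when_genetic_variances_zero(self):
        cfg = SimConfig(n_founders=300, n_generations=1, progeny_per_dam=2,
                        var_additive=0.0, var_pe=0.0, var_residual=0.5,
                        cg_effect_sd=0.0, age_class_effects={},
                        fescue_effect=0.0,
                        records_min=3, records_max=3, n_years=4, seed=12)
        ped = simulate_pedigree(cfg)
        rec, _ = simulate_phenotypes(ped, cfg)
        within = rec.groupby("animal_id")["score"].var(ddof=1).dropna()
        n = len(within)
        assert abs(within.mean() - 0.5) < 3 * 0.5 * np.sqrt(2 / 2) / np.sqrt(n)

    def test_fescue_contrast_recovered_in_group_means(self):
        cfg = SimConfig(n_founders=1500, n_generations=1, progeny_per_dam=2,
                        cg_effect_sd=0.0, age_class_effects={}, seed=13)
        ped = simulate_pedigree(cfg)
        rec, _ = simulate_phenotypes(ped, cfg)
        diff = (rec.loc[rec.fescue_status == "no", "score"].mean()
                - rec.loc[rec.fescue_status == "yes", "score"].mean())
        ses = rec.groupby("fescue_status")["score"].agg(["var", "size"])
        se = np.sqrt((ses["var"] / ses["size"]).sum())
        assert abs(diff - (-0.59)) < 3 * se

    def test_realized_ratios_match_configured_truth(self):
        cfg = SimConfig(n_founders=700, n_generations=1, progeny_per_dam=3, seed=14)
        ped = simulate_pedigree(cfg)
        _, truth = simulate_phenotypes(ped, cfg)
        assert abs(truth.realized_h2 - 0.40) < 0.05
        assert abs(truth.realized_repeatability - 0.442) < 0.05

    def test_discretized_scores_on_scale(self):
        cfg = SimConfig(n_founders=100, n_generations=1, discretize=True, seed=15)
        ped = simulate_pedigree(cfg)
        rec, _ = simulate_phenotypes(ped, cfg)
        assert rec["score"].isin([1, 2, 3, 4, 5]).all()

    def test_seed_reproducibility_bitwise(self):
        cfg = SimConfig(n_founders=50, n_generations=1, seed=16)
        ped = simulate_pedigree(cfg)
        r1, _ = simulate_phenotypes(ped, cfg)
        r2, _ = simulate_phenotypes(ped, cfg)
        pd.testing.assert_frame_equal(r1, r2)


class TestBivariateSims:
    def test_fescue_g0_matches_table_structure(self):
        g0 = default_fescue_g0(0.93)
        r = g0[0, 1] / np.sqrt(g0[0, 0] * g0[1, 1])
        assert r == pytest.approx(0.93)

    def test_zero_covariance_gives_uncorrelated_bvs(self):
        cfg = SimConfig(n_founders=1200, n_generations=1, progeny_per_dam=2, seed=17)
        ped = simulate_pedigree(cfg)
        g0 = np.diag([0.38, 0.30])
        _, truth = simulate_phenotypes_bivariate(ped, cfg, g0=g0)
        r = np.corrcoef(truth.true_bv["u_no"], truth.true_bv["u_yes"])[0, 1]
        assert abs(r) < 3 / np.sqrt(len(truth.true_bv))

    def test_maternal_truth_correlations_recovered_empirically(self):
        cfg = SimConfig(n_founders=500, n_generations=1, progeny_per_dam=2, seed=18)
        sim = simulate_ww_bivariate(simulate_pedigree(cfg), cfg)
        tb = sim.truth.true_bv
        n = len(tb)
        for a, b, target in (("m_hs", "m_ww", -0.19), ("u_ww", "m_ww", -0.43)):
            r = np.corrcoef(tb[a], tb[b])[0, 1]
            assert abs(r - target) < 3 / np.sqrt(n)

    def test_dummy_calves_have_unknown_sire_and_missing_weight(self):
        cfg = SimConfig(n_founders=60, n_generations=1, seed=19)
        sim = simulate_ww_bivariate(simulate_pedigree(cfg), cfg, calf_prob=0.5)
        ww = sim.ww_records
        dummy = ww[ww["weight"].isna()]
        assert len(dummy) > 0
        ped = sim.pedigree.table.set_index("animal")
        assert (ped.loc[dummy["calf_id"], "sire"] == "").all()
        # every dam-year has exactly one calf row
        hs = sim.hs_records
        assert len(ww) >= len(hs)

    def test_non_psd_covariance_rejected(self):
        cfg = SimConfig(n_founders=20, n_generations=1, seed=20)
        ped = simulate_pedigree(cfg)
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ConfigurationError):
            simulate_phenotypes_bivariate(ped, cfg, g0=bad)


def test_selected_population_shifts_breeding_values():
    cfg = SimConfig(n_founders=200, n_generations=2, progeny_per_dam=4,
                    selection=True, selection_fraction=0.3, seed=21)
    ped, bv = simulate_selected_population(cfg)
    gen = ped.table["generation"].to_numpy()
    # selection is downward (earlier shedding): mean BV decreases by generation
    assert bv[gen == 2].mean() < bv[gen == 0].mean() - 0.1
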