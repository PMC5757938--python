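"""Synthetic genotypes, pedigrees, traits and the experiment drivers."""

import numpy as np
import pytest
from scipy import stats

from wflm import (
    BasisSpec,
    FamilyStructure,
    PhenotypeData,
    SimScenario,
    WeightSpec,
    draw_effects,
    fit_null,
    flm_test,
    region_panel,
    run_power,
    run_type1,
    simulate_families,
    simulate_population_genotypes,
    simulate_trait,
)
from wflm.simulate import (
    RARE_MAF,
    effect_magnitude,
    nuclear_family_relationship,
    trait_cholesky,
)


class TestPopulationGenotypes:
    def test_sample_maf_tracks_generating_maf(self):
        region = simulate_population_genotypes(
            2000, 30, maf_sampler=lambda rng: 0.3, seed=5
        )
        se = np.sqrt(0.3 * 0.7 / (2 * 2000))
        assert np.all(np.abs(region.mafs - 0.3) < 5 * se)

    def test_deterministic_given_seed(self):
        r1 = simulate_population_genotypes(200, 25, seed=42, min_rare=5)
        r2 = simulate_population_genotypes(200, 25, seed=42, min_rare=5)
        np.testing.assert_array_equal(r1.G, r2.G)
        np.testing.assert_array_equal(r1.positions, r2.positions)

    def test_rare_variant_constraint_enforced(self):
        region = simulate_population_genotypes(700, 40, seed=3, min_rare=10)
        assert int(np.sum(region.mafs <= RARE_MAF)) >= 10
        assert region.m == 40
        assert np.all((region.mafs > 0) & (region.mafs <= 0.5))

    def test_ld_blocks_induce_correlation(self):
        flat = simulate_population_genotypes(
            3000, 10, maf_sampler=lambda rng: 0.3, seed=9
        )
        ld = simulate_population_genotypes(
            3000, 10, maf_sampler=lambda rng: 0.3, seed=9, ld_blocks=5
        )
        def mean_block_corr(region):
            C = np.corrcoef(region.G.T)
            return np.mean([C[i, j] for i in range(5) for j in range(i + 1, 5)])
        assert mean_block_corr(ld) > mean_block_corr(flat) + 0.2


class TestFamilies:
    def test_relationship_matrix_matches_kinship_theory(self):
        R = nuclear_family_relationship(3, FamilyStructure(2))
        fam = R.R[:4, :4]
        assert fam[0, 1] == 0.0  # founders unrelated
        assert fam[0, 2] == fam[1, 3] == 0.5  # parent-offspring
        assert fam[2, 3] == 0.5  # full sibs
        np.testing.assert_array_equal(np.diag(R.R), 1.0)
        assert np.all(R.R[:4, 4:] == 0.0)  # block-diagonal across families

    def test_gene_dropping_conserves_allele_frequency(self):
        region, R = simulate_families(
            400, FamilyStructure(4), maf_sampler=lambda rng: 0.2, m=30, seed=11
        )
        offspring = np.array(["_o" in s for s in region.ids])
        freq = region.G[offspring].mean(axis=0) / 2
        # offspring pooled frequency should match the founder MAF
        se = np.sqrt(0.2 * 0.8 / (2 * offspring.sum() / 2))  # sibs correlated: ~2x SE
        assert np.all(np.abs(freq - 0.2) < 5 * se)

    def test_deterministic_given_seed(self):
        r1, _ = simulate_families(30, m=20, seed=7)
        r2, _ = simulate_families(30, m=20, seed=7)
        np.testing.assert_array_equal(r1.G, r2.G)


class TestEffects:
    def test_effect_laws_closed_form(self):
        assert np.isclose(effect_magnitude([0.01], "log_maf", 2.0)[0], np.log(2.0))
        assert np.isclose(
            effect_magnitude([0.5], "variance_standardized", 0.1)[0], 0.1 / np.sqrt(0.5)
        )

    def test_causal_count_and_signs(self, rng):
        region = simulate_population_genotypes(500, 40, seed=rng, min_rare=12)
        sc = SimScenario(prop_causal=0.5, prop_same_direction=1.0, causal_pool="rare_only")
        eff = draw_effects(region, sc, seed=1)
        pool = int(np.sum(region.mafs <= RARE_MAF))
        assert eff.causal_idx.size == round(0.5 * pool)
        assert np.all(eff.beta[eff.causal_idx] > 0)  # all same direction
        assert np.all(np.delete(eff.beta, eff.causal_idx) == 0)
        sc_mixed = SimScenario(prop_causal=1.0, prop_same_direction=0.5,
                               causal_pool="rare_only")
        eff2 = draw_effects(region, sc_mixed, seed=2)
        n_pos = int(np.sum(eff2.beta[eff2.causal_idx] > 0))
        assert n_pos == round(0.5 * pool)

    def test_empty_pool_rejected(self, rng):
        from conftest import make_dense_region

        region = make_dense_region(rng, 400, 6, low=0.3, high=0.45)
        with pytest.raises(ValueError, match="empty"):
            draw_effects(region, SimScenario(prop_causal=0.2), seed=0)


class TestTrait:
    def test_null_population_trait_is_standard_normal(self):
        region = simulate_population_genotypes(5000, 10, seed=21)
        y = simulate_trait(region, None, 0.0, None, seed=22)
        assert abs(y.mean()) < 0.05 and abs(y.var() - 1.0) < 0.06

    def test_sib_pair_covariance_matches_model(self):
        """cov(sibs) = h2 * 0.5 under the null at h2 = 0.29."""
        n_fam = 300
        R = nuclear_family_relationship(n_fam, FamilyStructure(2))
        n = R.ids.size
        L = trait_cholesky(0.29, R, n)
        rng = np.random.default_rng(33)
        Y = L @ rng.standard_normal((n, 2000))
        sib1 = Y[2::4]  # first offspring of each family
        sib2 = Y[3::4]
        cov = np.mean(sib1 * sib2) - np.mean(sib1) * np.mean(sib2)
        assert abs(cov - 0.145) < 0.02

    def test_reproducible_and_mean_shift(self):
        region = simulate_population_genotypes(300, 20, seed=1)
        beta = np.zeros(region.m)
        beta[0] = 1.0
        y1 = simulate_trait(region, beta, 0.0, None, seed=5)
        y2 = simulate_trait(region, beta, 0.0, None, seed=5)
        np.testing.assert_array_equal(y1, y2)
        y0 = simulate_trait(region, None, 0.0, None, seed=5)
        np.testing.assert_allclose(y1 - y0, region.G @ beta, atol=1e-12)


class TestDrivers:
    def test_type1_edge_alphas(self):
        res = run_type1("population", BasisSpec("fourier", 9), None, 200,
                        alphas=(1.0, 0.0), seed=2, n_target=150, n_regions=4,
                        m_range=(30, 35))
        assert res.rates[1.0] == 1.0
        assert res.rates[0.0] == 0.0

    def test_null_pvalues_uniform_population(self):
        res = run_type1("population", BasisSpec("bspline", 15), WeightSpec(1, 25),
                        4000, alphas=(0.05,), seed=8, n_target=400, n_regions=10)
        assert stats.kstest(res.pvalues, "uniform").pvalue > 0.01

    def test_null_pvalues_uniform_family(self):
        res = run_type1("family", BasisSpec("fourier", 25), WeightSpec(1, 25),
                        1500, alphas=(0.05,), seed=9, n_target=420, n_regions=8)
        assert stats.kstest(res.pvalues, "uniform").pvalue > 0.01

    def test_family_scan_agrees_with_flm_test(self):
        """The vectorized eigen-space driver computes the same P value as the
        public per-region test on the same trait."""
        from wflm.simulate import _family_scan, _region_designs

        regions, R = region_panel("family", 120, 2, m_range=(30, 32), seed=14)
        spec, wspec = BasisSpec("bspline", 15), WeightSpec(1, 25)
        designs = _region_designs(regions, None, spec, wspec)
        U, d = R.eigendecomposition()
        rng = np.random.default_rng(77)
        pvals = _family_scan(regions, R, designs, 3, rng, 0.29)
        # replay the same stream to reconstruct the traits
        rng2 = np.random.default_rng(77)
        assign = rng2.integers(0, len(regions), size=3)
        for i in range(3):
            y_t = np.sqrt(0.29 * d + 0.71) * rng2.standard_normal(R.ids.size)
            y = U @ y_t
            reg = regions[assign[i]]
            data = PhenotypeData(reg.ids, y, np.ones((reg.n, 1)))
            fit = fit_null(data, R)
            res = flm_test(reg, data, fit, None, spec, wspec)
            np.testing.assert_allclose(pvals[i], res.p_value, rtol=1e-6)

    def test_power_approaches_alpha_for_vanishing_effects(self):
        sc = SimScenario(prop_causal=0.1, s=1.0 + 1e-12, effect_model="log_maf",
                        n_replicates=300)
        res = run_power(sc, "population", BasisSpec("fourier", 9), None, seed=3,
                        threshold=0.1, n_target=200, n_regions=4)
        se = np.sqrt(0.1 * 0.9 / 300)
        assert abs(res.power - 0.1) < 4 * se

    def test_experiments_reproducible(self):
        r1 = run_type1("population", BasisSpec("fourier", 9), None, 300, (0.05,),
                       seed=6, n_target=150, n_regions=3)
        r2 = run_type1("population", BasisSpec("fourier", 9), None, 300, (0.05,),
                       seed=6, n_target=150, n_regions=3)
        np.testing.assert_array_equal(r1.pvalues, r2.pvalues)
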