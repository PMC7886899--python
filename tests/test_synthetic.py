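"""Synthetic-cohort generator: LD sampler, mating, phenotype model."""
import numpy as np
import pandas as pd
import pytest

from relcov import (SimConfig, StratConfig, founder_cohort,
                    generate_phenotypes, haplotype_frequencies,
                    match_mates, max_tagging_r2, relative_pairs_by_class,
                    simulate_cohort, simulate_covariate_stratification,
                    simulate_founder_genotypes)
from relcov.simulate import simulate_relative_cliques

from conftest import standardized_phenotype


# ---------------------------------------------------------------------------
# founder genotypes and two-locus LD
# ---------------------------------------------------------------------------

class TestFounderLD:
    def test_haplotype_frequency_oracle(self):
        """The sampler's haplotype table reproduces the target r^2 exactly
        (brute-force two-locus enumeration)."""
        for pc, pm, r2 in [(0.05, 0.1, 0.4), (0.2, 0.3, 0.25),
                           (0.4, 0.4, 0.9)]:
            hf = haplotype_frequencies(pc, pm, r2)
            assert abs(sum(hf.values()) - 1.0) < 1e-12
            # dosage correlation equals haplotype-allele correlation
            d = hf["AB"] - pc * pm
            r2_exact = d * d / (pc * (1 - pc) * pm * (1 - pm))
            assert r2_exact == pytest.approx(r2, abs=1e-12)

    def test_empirical_r2_matches_target(self):
        cfg = SimConfig(n_individuals=20_000, n_causal=5, n_markers=10,
                        maf_causal_range=(0.05, 0.05),
                        maf_marker_range=(0.1, 0.1),
                        tagging_r2=0.4, seed=1)
        g = simulate_founder_genotypes(cfg)
        for c in range(5):
            t = g.tag_of[c]
            r2 = np.corrcoef(g.dosages[:, c], g.dosages[:, t])[0, 1] ** 2
            assert r2 == pytest.approx(0.4, abs=0.05)

    def test_perfect_ld_identical_dosages(self):
        cfg = SimConfig(n_individuals=500, n_causal=4, n_markers=8,
                        tagging_r2=1.0, seed=2)
        g = simulate_founder_genotypes(cfg)
        for c in range(4):
            assert np.array_equal(g.dosages[:, c], g.dosages[:, g.tag_of[c]])

    def test_zero_ld_independent(self):
        cfg = SimConfig(n_individuals=10_000, n_causal=4, n_markers=8,
                        maf_causal_range=(0.2, 0.4),
                        maf_marker_range=(0.2, 0.4),
                        tagging_r2=0.0, seed=3)
        g = simulate_founder_genotypes(cfg)
        for c in range(4):
            r = np.corrcoef(g.dosages[:, c], g.dosages[:, g.tag_of[c]])[0, 1]
            assert abs(r) < 3.0 / np.sqrt(cfg.n_individuals) + 0.02

    def test_infeasible_r2_raises_with_bound(self):
        with pytest.raises(ValueError, match="maximum attainable"):
            haplotype_frequencies(0.05, 0.3, 0.4)
        cfg = SimConfig(n_individuals=100, n_causal=2, n_markers=4,
                        maf_causal_range=(0.05, 0.05),
                        maf_marker_range=(0.3, 0.3),
                        tagging_r2=0.4, seed=1)
        with pytest.raises(ValueError, match="maximum attainable"):
            simulate_founder_genotypes(cfg)
        assert max_tagging_r2(0.05, 0.3) < 0.4


# ---------------------------------------------------------------------------
# mate matching and the AM generation loop
# ---------------------------------------------------------------------------

class TestAssortativeMating:
    def test_random_mating_near_zero_correlation(self, rng):
        y = rng.normal(size=5000)
        ia, ib, r = match_mates(y, 0.0, rng)
        assert abs(r) < 3.0 / np.sqrt(len(ia))

    @pytest.mark.parametrize("target", [0.24, 0.6, -0.3])
    def test_matching_hits_target(self, rng, target):
        y = rng.normal(size=8000)
        ia, ib, r = match_mates(y, target, rng)
        assert r == pytest.approx(target, abs=0.02)

    def test_realised_spousal_r_over_generations(self, am_cohort_mid):
        cfg, cohort = am_cohort_mid
        realised = cohort.history["spousal_r_realised"].dropna()
        assert realised.iloc[-1] == pytest.approx(0.24, abs=0.03)

    def test_am_inflates_additive_variance(self, am_cohort_mid):
        cfg, cohort = am_cohort_mid
        va = cohort.history["var_additive"].to_numpy()
        assert va[-1] > va[0]
        # plateau: late-generation mean close to the final value
        assert np.mean(va[-4:]) == pytest.approx(va[-1], rel=0.05)

    def test_equilibrium_identity_for_fullsib_designs(self, am_cohort_mid):
        """V_A(random mating)/V_P(equilibrium) = h2_EQ (1 - r h2_EQ)."""
        cfg, cohort = am_cohort_mid
        hist = cohort.history
        h2_eq = hist.iloc[-1]["var_additive"] / hist.iloc[-1]["var_phenotype"]
        ratio = cfg.h2_rm / hist.iloc[-1]["var_phenotype"]
        expected = h2_eq * (1 - 0.24 * h2_eq)
        assert ratio == pytest.approx(expected, abs=0.05)

    def test_population_too_small(self):
        with pytest.raises(ValueError):
            match_mates(np.array([1.0, 2.0]), 0.2,
                        np.random.default_rng(0))


# ---------------------------------------------------------------------------
# phenotype model
# ---------------------------------------------------------------------------

class TestPhenotypes:
    def test_generation0_variance_partition(self):
        cfg = SimConfig(n_individuals=20_000, n_causal=100, n_markers=100,
                        h2_rm=0.5, c2=0.2, v_aa=0.1, spousal_r=0.0,
                        n_generations=1, seed=11)
        rng = np.random.default_rng(11)
        coh = founder_cohort(cfg, rng)
        generate_phenotypes(coh, cfg, rng)
        comp = coh.components
        assert comp["phenotype"].var() == pytest.approx(1.0, abs=0.05)
        assert comp["additive"].var() == pytest.approx(0.5, abs=0.02)
        assert comp["epistatic"].var() == pytest.approx(0.1, abs=0.02)
        assert comp["shared_env"].var() == pytest.approx(0.2, abs=0.02)
        recon = (comp["additive"] + comp["epistatic"] + comp["shared_env"]
                 + comp["residual"])
        assert np.allclose(recon, comp["phenotype"])

    def test_null_heritability_pure_noise(self):
        cfg = SimConfig(n_individuals=5_000, n_causal=50, n_markers=50,
                        h2_rm=0.0, c2=0.0, v_aa=0.0, spousal_r=0.0,
                        n_generations=1, seed=12)
        rng = np.random.default_rng(12)
        coh = founder_cohort(cfg, rng)
        generate_phenotypes(coh, cfg, rng)
        assert np.all(coh.components["additive"] == 0)

    def test_sib_cross_product_under_random_mating(self, twin_cohort):
        """Mean sib cross-product = c2 + 0.5 h2 in the ACE model."""
        cfg, cohort = twin_cohort
        G = cfg.n_generations
        ped = cohort.pedigree
        last = ped[ped["generation"] == G]
        ids = last["iid"].to_numpy()
        y = standardized_phenotype(cohort, ids)
        classes = relative_pairs_by_class(ped, ids)
        ia, ib, _ = classes["fullsib"]
        cp = (y[ia] * y[ib]).mean()
        expected = cfg.c2 + 0.5 * cfg.h2_rm
        assert cp == pytest.approx(expected, abs=0.06)

    def test_mz_twins_share_dosages_and_correlation(self, twin_cohort):
        cfg, cohort = twin_cohort
        G = cfg.n_generations
        ped = cohort.pedigree.set_index("iid")
        mz = cohort.pedigree[(cohort.pedigree["twin"] == "mz")
                             & (cohort.pedigree["generation"] == G)]
        fams = mz.groupby("family")["iid"].apply(list)
        geno = cohort.genotypes
        pos = {int(i): k for k, i in enumerate(geno.individual_ids)}
        a_ids = np.array([f[0] for f in fams if len(f) >= 2])
        b_ids = np.array([f[1] for f in fams if len(f) >= 2])
        for a, b in zip(a_ids[:50], b_ids[:50]):
            assert np.array_equal(geno.dosages[pos[a]], geno.dosages[pos[b]])
        ally = standardized_phenotype(
            cohort, cohort.pedigree.loc[
                cohort.pedigree["generation"] == G, "iid"].to_numpy())
        idx = {int(i): k for k, i in enumerate(
            cohort.pedigree.loc[cohort.pedigree["generation"] == G,
                                "iid"].to_numpy())}
        r_mz = np.mean([ally[idx[a]] * ally[idx[b]]
                        for a, b in zip(a_ids, b_ids)])
        # r_MZ = h2 + c2 under random mating
        assert r_mz == pytest.approx(cfg.h2_rm + cfg.c2, abs=0.08)

    def test_sib_ibd_mean_half(self, twin_cohort):
        cfg, cohort = twin_cohort
        sib = cohort.sib_ibd
        non_mz = sib[sib["ibd"] < 1.0]
        assert non_mz["ibd"].mean() == pytest.approx(0.5, abs=0.01)


# ---------------------------------------------------------------------------
# covariate stratification
# ---------------------------------------------------------------------------

class TestStratification:
    def _strat_cohort(self, cg_share, seed=21, n=6000):
        cfg = SimConfig(n_individuals=n, n_causal=50, n_markers=200,
                        h2_rm=0.4, spousal_r=0.0, n_generations=1,
                        seed=seed)
        rng = np.random.default_rng(seed)
        coh = founder_cohort(cfg, rng)
        generate_phenotypes(coh, cfg, rng)
        strat = StratConfig(n_cg=378, cg_share=cg_share, batch_share=0.0,
                            pc_share=0.0)
        return simulate_covariate_stratification(coh, strat, rng)

    def test_zero_injected_cg_share(self):
        from relcov import partial_r2
        coh = self._strat_cohort(0.0)
        table = coh.covariates.copy()
        table["y"] = coh.components["phenotype"].to_numpy()
        r2 = partial_r2(table, "cg", baseline_model=1)
        # 378 levels absorb some variance by chance alone
        assert r2 < 378 / len(table) * 2

    def test_injected_cg_share_recovered(self):
        from relcov import partial_r2
        coh = self._strat_cohort(0.05, n=10_000)
        table = coh.covariates.copy()
        table["y"] = coh.components["phenotype"].to_numpy()
        r2 = partial_r2(table, "cg", baseline_model=1)
        overhead = 378 / len(table)        # chance absorption by 378 levels
        assert r2 - overhead == pytest.approx(0.05, abs=0.025)

    def test_378_contemporary_groups(self):
        coh = self._strat_cohort(0.02)
        assert coh.covariates["cg"].nunique() <= 378
        assert coh.covariates["cg"].nunique() > 300
        assert coh.strat_injected["cg_share"] == 0.02

    def test_share_sum_validation(self):
        with pytest.raises(ValueError):
            StratConfig(cg_share=0.6, batch_share=0.3, pc_share=0.2)


# ---------------------------------------------------------------------------
# relative cliques
# ---------------------------------------------------------------------------

class TestRelativeCliques:
    def test_template_kinship_classes(self):
        cfg = SimConfig(n_individuals=10, n_causal=40, n_markers=0,
                        h2_rm=0.5, spousal_r=0.0, n_generations=1, seed=5)
        coh = simulate_relative_cliques(cfg, n_families=50,
                                        rng=np.random.default_rng(5))
        from relcov.workflows import template_class_pairs
        classes = template_class_pairs(coh)
        assert set(np.round(list(classes), 6)) == {
            0.5, 0.25, 0.125, 0.0625, 0.03125}

    def test_realised_sharing_matches_expectation(self):
        """Mean realised genomic relationship per class ~ pedigree pi."""
        cfg = SimConfig(n_individuals=10, n_causal=500, n_markers=0,
                        maf_causal_range=(0.2, 0.5), h2_rm=0.5,
                        spousal_r=0.0, n_generations=1, seed=6)
        coh = simulate_relative_cliques(cfg, n_families=80,
                                        rng=np.random.default_rng(6))
        from relcov.workflows import template_class_pairs
        from relcov import compute_grm
        grm = compute_grm(coh.genotypes)
        classes = template_class_pairs(coh)
        for pi, (ia, ib) in classes.items():
            mean_pi = grm.values[ia, ib].mean()
            assert mean_pi == pytest.approx(pi, abs=0.02)
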