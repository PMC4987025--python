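"""Synthetic-cohort generator: structure, determinism, and moments."""

import numpy as np
import pandas as pd
import pytest

from pedmix import (
    CohortDesign,
    GwasTruth,
    SimulationTruth,
    additive_relationship_matrix,
    parse_pedigree,
    realize_gwas,
    simulate_breeding_values,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_target_genotypes,
    simulate_training_gwas,
)
from pedmix.simulate import write_cohort_tables

from .conftest import random_pedigree


class TestPedigreeSimulation:
    def test_two_generation_counting(self):
        design = CohortDesign(n_families=10, generations=2,
                              mean_offspring=2, offspring_dist="constant")
        ped = simulate_pedigree(design, seed=1)
        assert len(ped) == 10 * 4  # 2 founders + 2 offspring per family
        assert len(ped.couples) == 10

    def test_determinism_byte_identical_files(self, tmp_path):
        design = CohortDesign(n_families=15, generations=3)
        for sub in ("a", "b"):
            ped = simulate_pedigree(design, seed=77)
            write_cohort_tables(ped, tmp_path / sub)
        for name in ("pedigree.tsv", "couples.tsv", "households.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_deep_pedigree_matches_oracle(self):
        from .conftest import kinship_oracle

        design = CohortDesign(n_families=3, generations=5, couple_rate=1.0)
        ped = simulate_pedigree(design, seed=3)
        A = additive_relationship_matrix(ped)
        ids, expected = kinship_oracle(ped)
        np.testing.assert_allclose(
            A.reordered(list(ids)).to_dense(), expected, atol=1e-12
        )
        # great-grandparent chains exist and are related
        assert (expected[~np.eye(len(ids), dtype=bool)] > 0).any()

    def test_roundtrip_through_parser(self, tmp_path):
        ped = simulate_pedigree(CohortDesign(n_families=5), seed=9)
        paths = write_cohort_tables(ped, tmp_path)
        ped2 = parse_pedigree(paths["pedigree"], couples_file=paths["couples"],
                              households_file=paths["households"])
        assert ped2.ids == ped.ids
        assert sorted(ped2.couples) == sorted(ped.couples)
        assert ped2.households == ped.households


class TestBreedingValues:
    def test_zero_variance_gives_zeros(self, fullsib_mating):
        vals = simulate_breeding_values(fullsib_mating, 0.0, seed=1)
        np.testing.assert_array_equal(vals, np.zeros_like(vals))

    def test_perfect_genetic_correlation(self, fullsib_mating):
        G = np.array([[0.5, 0.5], [0.5, 0.5]])  # rg = 1, equal variances
        vals = simulate_breeding_values(fullsib_mating, G, seed=2)
        np.testing.assert_allclose(vals[:, 0], vals[:, 1], atol=1e-12)

    def test_covariance_matches_sigma2_A(self):
        ped = random_pedigree(7, max_size=10)
        sigma2 = 0.8
        R = 4000
        reps = simulate_breeding_values(ped, sigma2, seed=3, n_replicates=R)
        emp = np.cov(reps[:, :, 0].T)
        A = additive_relationship_matrix(ped).reordered(ped.ids).to_dense()
        # entrywise within 3 Monte Carlo SEs
        target = sigma2 * A
        mc_se = np.sqrt((np.outer(np.diag(target), np.diag(target))
                         + target**2) / R)
        assert np.all(np.abs(emp - target) < 3.5 * mc_se)

    def test_negative_variance_rejected(self, trio):
        with pytest.raises(ValueError):
            simulate_breeding_values(trio, -1.0, seed=1)


class TestPhenotypes:
    def test_degenerate_thresholds_single_grade(self, trio):
        truth = SimulationTruth(
            var_additive=0.0, var_spouse=0.0, var_residual=1.0,
            thresholds=(-4e9, -3e9, -2e9, -1e9),
        )
        phe = simulate_phenotypes(trio, truth, seed=1)
        assert (phe["cpg"] == 4).all()

    def test_grade_frequencies_and_prevalence(self, small_cohort):
        phe = small_cohort["phenotypes"]
        truth = small_cohort["truth"]
        freqs = phe["cpg"].value_counts(normalize=True).sort_index()
        np.testing.assert_allclose(freqs.to_numpy(), truth.grade_freqs, atol=0.01)
        assert abs(phe["mdd"].mean() - truth.prevalence_mdd) < 0.01

    def test_spouse_pairs_more_concordant_than_random(self):
        ped = simulate_pedigree(CohortDesign(n_families=320), seed=5)
        truth = SimulationTruth()  # h2 0.4, spouse share 0.2
        phe = simulate_phenotypes(ped, truth, seed=6).set_index("id")
        grades = phe["cpg"]
        pairs = np.array([
            [grades.loc[a], grades.loc[b]] for a, b in ped.couples
        ], dtype=float)
        r_spouse = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
        rng = np.random.default_rng(0)
        null = []
        flat = grades.to_numpy(dtype=float)
        for _ in range(500):
            perm = rng.permutation(len(flat))
            null.append(np.corrcoef(flat[perm[: len(pairs)]],
                                    flat[perm[len(pairs): 2 * len(pairs)]])[0, 1])
        # one-sided: observed spouse correlation beyond the null at alpha=0.01
        assert r_spouse > np.quantile(null, 0.99)

    def test_cross_trait_genetic_correlation(self):
        ped = simulate_pedigree(CohortDesign(n_families=1100), seed=7)
        truth = SimulationTruth(rg=0.5)
        _, parts = simulate_phenotypes(ped, truth, seed=8, return_components=True)
        g = parts["genetic"]
        r = np.corrcoef(g[:, 0], g[:, 1])[0, 1]
        assert abs(r - 0.5) < 0.03  # n ~ 10,000

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            SimulationTruth(thresholds=(0.0, 0.0, 1.0, 2.0))


class TestGenotypes:
    def test_hwe_frequencies(self):
        from pedmix.pedigree import Individual, Pedigree

        ped = Pedigree(individuals=[
            Individual(f"I{k}", None, None, "unknown") for k in range(10_000)
        ])
        gwas = realize_gwas(GwasTruth(n_snps=1, n_causal=0, maf_range=(0.5, 0.5)), seed=1)
        geno = simulate_target_genotypes(ped, gwas, seed=2)
        counts = np.bincount(geno.dosages[:, 0].astype(int), minlength=3) / 10_000
        se = np.sqrt(np.array([0.25, 0.5, 0.25]) * 0.75 / 10_000)
        assert np.all(np.abs(counts - [0.25, 0.5, 0.25]) < 4 * se)

    def test_mendelian_transmission(self):
        ped = simulate_pedigree(CohortDesign(n_families=60), seed=3)
        gwas = realize_gwas(GwasTruth(n_snps=50, n_causal=10, maf_range=(0.1, 0.4)), seed=4)
        geno = simulate_target_genotypes(ped, gwas, seed=5)
        idx = {iid: k for k, iid in enumerate(geno.ids)}
        dos = geno.dosages
        for ind in ped.individuals:
            if ind.father is None or ind.mother is None:
                continue
            child = dos[idx[ind.id]]
            pa, ma = dos[idx[ind.father]], dos[idx[ind.mother]]
            both_zero = (pa == 0) & (ma == 0)
            assert np.all(child[both_zero] == 0)
            both_two = (pa == 2) & (ma == 2)
            assert np.all(child[both_two] == 2)

    def test_vcf_determinism(self, tmp_path, trio):
        from pedmix import write_vcf

        gwas = GwasTruth(n_snps=20, n_causal=5)
        blobs = []
        for sub in ("a.vcf", "b.vcf"):
            geno = simulate_target_genotypes(trio, gwas, seed=42)
            write_vcf(geno, tmp_path / sub)
            blobs.append((tmp_path / sub).read_bytes())
        assert blobs[0] == blobs[1]


class TestTrainingGwas:
    def test_null_pvalues_uniform(self):
        gwas = GwasTruth(n_snps=2000, n_causal=0, h2_snp=0.0, n_train=800)
        stats = simulate_training_gwas(gwas, seed=11)
        from scipy.stats import kstest

        assert kstest(stats["P"], "uniform").pvalue > 0.01

    def test_large_effect_recovered(self):
        gwas = realize_gwas(
            GwasTruth(n_snps=100, n_causal=5, h2_snp=0.4, n_train=20_000),
            seed=12,
        )
        stats = simulate_training_gwas(gwas, seed=13)
        beta_true = np.asarray(gwas.true_beta)
        top = int(np.argmax(np.abs(beta_true)))
        row = stats.iloc[top]
        assert abs(row["BETA"] - beta_true[top]) < 3 * row["SE"]

    def test_deterministic(self):
        gwas = GwasTruth(n_snps=50, n_causal=10, n_train=500)
        a = simulate_training_gwas(gwas, seed=14)
        b = simulate_training_gwas(gwas, seed=14)
        pd.testing.assert_frame_equal(a, b)
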