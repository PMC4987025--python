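"""Polygenic scoring: parsing, allele alignment, thresholding, ancestry
components, association and variance explained."""

import numpy as np
import pandas as pd
import pytest

from pedmix import (
    CohortDesign,
    GenotypeMatrix,
    GwasTruth,
    SummaryStats,
    additive_relationship_matrix,
    align_alleles,
    ancestry_components,
    prs_mixed_association,
    prs_variance_explained,
    read_genotypes,
    read_summary_stats,
    realize_gwas,
    simulate_pedigree,
    simulate_target_genotypes,
    simulate_training_gwas,
    threshold_and_score,
    write_dosage_tsv,
    write_vcf,
)
from pedmix.prs import GenotypeFormatError, SummaryStatsError


def _stats(rows):
    return SummaryStats(table=pd.DataFrame(
        rows, columns=["snp", "effect_allele", "other_allele", "weight", "p"]
    ))


def _geno(snp_ids, a1, a2, dosages, ids=None):
    dosages = np.asarray(dosages, dtype=np.float32)
    ids = ids or tuple(f"I{k}" for k in range(dosages.shape[0]))
    return GenotypeMatrix(ids=tuple(ids), snp_ids=tuple(snp_ids),
                          counted_allele=tuple(a1), other_allele=tuple(a2),
                          dosages=dosages)


class TestSummaryStats:
    def test_read_well_formed(self, tmp_path):
        p = tmp_path / "ss.tsv"
        p.write_text("SNP\tA1\tA2\tBETA\tP\n"
                     "rs1\tA\tG\t0.1\t0.5\n"
                     "rs2\tC\tT\t-0.2\t0.01\n"
                     "rs3\tG\tT\t0.05\t1.0\n"
                     "rs4\tA\tC\t0.0\t0.9\n")
        ss = read_summary_stats(p)
        assert len(ss) == 4

    def test_duplicate_snp_named(self):
        with pytest.raises(SummaryStatsError, match="rs1"):
            _stats([("rs1", "A", "G", 0.1, 0.5), ("rs1", "C", "T", 0.2, 0.1)])

    def test_p_zero_rejected(self):
        with pytest.raises(SummaryStatsError, match=r"\(0, 1\]"):
            _stats([("rs1", "A", "G", 0.1, 0.0)])

    def test_missing_column(self, tmp_path):
        p = tmp_path / "ss.tsv"
        p.write_text("SNP\tA1\tBETA\tP\nrs1\tA\t0.1\t0.5\n")
        with pytest.raises(SummaryStatsError, match="A2"):
            read_summary_stats(p)

    def test_column_map(self, tmp_path):
        p = tmp_path / "ss.tsv"
        p.write_text("marker\tea\toa\tlogodds\tpval\nrs1\tA\tG\t0.1\t0.5\n")
        ss = read_summary_stats(p, column_map={
            "snp": "marker", "effect_allele": "ea", "other_allele": "oa",
            "weight": "logodds", "p": "pval",
        })
        assert ss.table.iloc[0]["snp"] == "rs1"


class TestGenotypeIO:
    def test_vcf_gt_conversion(self, tmp_path):
        p = tmp_path / "g.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
            "1\t1\trs1\tG\tA\t.\tPASS\t.\tGT\t0/1\t1|1\t./.\n"
        )
        g = read_genotypes(p, format="vcf")
        assert g.counted_allele == ("A",)
        assert g.dosages[0, 0] == 1.0
        assert g.dosages[1, 0] == 2.0
        assert np.isnan(g.dosages[2, 0])

    def test_malformed_line_reports_lineno(self, tmp_path):
        p = tmp_path / "g.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t1\trs1\tG\tA\t.\tPASS\t.\tGT\t0/1\textra\n"
        )
        with pytest.raises(GenotypeFormatError, match=":3:"):
            read_genotypes(p, format="vcf")

    def test_roundtrip_vcf_and_dosage(self, tmp_path, trio):
        gwas = GwasTruth(n_snps=30, n_causal=5)
        geno = simulate_target_genotypes(trio, gwas, seed=8, missing_rate=0.1)
        write_vcf(geno, tmp_path / "g.vcf")
        write_dosage_tsv(geno, tmp_path / "g.tsv")
        for fmt, path in (("vcf", "g.vcf"), ("dosage_tsv", "g.tsv")):
            back = read_genotypes(tmp_path / path, format=fmt)
            assert back.ids == geno.ids
            assert back.snp_ids == geno.snp_ids
            assert back.counted_allele == geno.counted_allele
            np.testing.assert_array_equal(
                np.isnan(back.dosages), np.isnan(geno.dosages))
            np.testing.assert_allclose(
                np.nan_to_num(back.dosages), np.nan_to_num(geno.dosages))


class TestAlignment:
    def test_swapped_alleles_negate_weight(self):
        ss = _stats([("rs1", "A", "G", 0.4, 0.5)])
        g = _geno(["rs1"], ["G"], ["A"], [[2.0], [0.0]])
        al = align_alleles(ss, g)
        assert al.weights[0] == -0.4

    def test_ambiguous_excluded(self):
        ss = _stats([("rs1", "A", "T", 0.4, 0.5), ("rs2", "C", "G", 0.1, 0.5),
                     ("rs3", "A", "G", 0.2, 0.5)])
        g = _geno(["rs1", "rs2", "rs3"], ["A", "C", "A"], ["T", "G", "G"],
                  [[1, 1, 1]])
        al = align_alleles(ss, g)
        assert dict(al.exclusions) == {"rs1": "strand-ambiguous",
                                       "rs2": "strand-ambiguous"}
        assert list(al.snp_index) == [2]

    def test_mismatch_excluded(self):
        ss = _stats([("rs1", "A", "G", 0.4, 0.5)])
        g = _geno(["rs1"], ["C"], ["T"], [[1.0]])
        al = align_alleles(ss, g)
        assert al.exclusions == [("rs1", "allele-mismatch")]

    def test_empty_overlap(self):
        ss = _stats([("rs9", "A", "G", 0.4, 0.5)])
        g = _geno(["rs1"], ["A"], ["G"], [[1.0]])
        with pytest.raises(SummaryStatsError, match="overlap"):
            align_alleles(ss, g)

    def test_flip_invariance_of_scores(self):
        rng = np.random.default_rng(4)
        n, m = 50, 20
        dosages = rng.integers(0, 3, size=(n, m)).astype(np.float32)
        a1 = ["A"] * m
        a2 = ["G"] * m
        weights = rng.normal(size=m)
        ps = rng.uniform(0.001, 1, size=m)
        ss = _stats([(f"rs{j}", "A", "G", weights[j], ps[j]) for j in range(m)])
        g1 = _geno([f"rs{j}" for j in range(m)], a1, a2, dosages)
        # flip allele labels (and dosages) for half of the SNPs
        flip = np.arange(m) % 2 == 0
        d2 = dosages.copy()
        d2[:, flip] = 2.0 - d2[:, flip]
        g2 = _geno([f"rs{j}" for j in range(m)],
                   ["G" if f else "A" for f in flip],
                   ["A" if f else "G" for f in flip], d2)
        s1 = threshold_and_score(ss, g1, thresholds=(0.5,))
        s2 = threshold_and_score(ss, g2, thresholds=(0.5,))
        np.testing.assert_allclose(s1.standardized[0.5], s2.standardized[0.5],
                                   atol=1e-5)


class TestScoring:
    def test_threshold_counting(self):
        ps = [0.001, 0.03, 0.2, 0.6]
        ss = _stats([(f"rs{j}", "A", "G", 0.1, p) for j, p in enumerate(ps)])
        g = _geno([f"rs{j}" for j in range(4)], ["A"] * 4, ["G"] * 4,
                  np.ones((3, 4)))
        prof = threshold_and_score(ss, g, thresholds=(0.05,))
        assert prof.n_snps_used[0.05] == 2

    def test_score_arithmetic(self):
        ss = _stats([("rs0", "A", "G", 0.2, 0.01), ("rs1", "A", "G", -0.1, 0.01)])
        g = _geno(["rs0", "rs1"], ["A", "A"], ["G", "G"], [[2.0, 1.0]])
        prof = threshold_and_score(ss, g, thresholds=(0.05,))
        assert prof.raw[0.05][0] == pytest.approx(0.3)

    def test_missing_imputed_at_twice_frequency(self):
        ss = _stats([("rs0", "A", "G", 0.5, 0.01), ("rs1", "A", "G", 1.0, 0.01)])
        d = np.array([[1.0, np.nan], [1.0, np.nan], [1.0, np.nan]])
        g = _geno(["rs0", "rs1"], ["A", "A"], ["G", "G"], d)
        prof = threshold_and_score(ss, g, thresholds=(0.05,))
        # rs1 all-missing: imputed dosage 0 (frequency undefined -> 0),
        # contributing identically to everyone => zero SD contribution
        assert np.ptp(prof.raw[0.05]) == pytest.approx(0.0)

    def test_empty_threshold_warns_and_omits(self):
        ss = _stats([("rs0", "A", "G", 0.2, 0.9)])
        g = _geno(["rs0"], ["A"], ["G"], [[1.0], [0.0]])
        with pytest.warns(UserWarning, match="retains no SNPs"):
            prof = threshold_and_score(ss, g, thresholds=(0.01, 0.95))
        assert 0.01 not in prof.raw
        assert 0.95 in prof.raw

    def test_monotone_snp_inclusion(self):
        gwas = realize_gwas(GwasTruth(n_snps=400, n_causal=40, n_train=500), seed=1)
        stats = simulate_training_gwas(gwas, seed=2)
        ss = SummaryStats(table=stats.rename(columns={
            "SNP": "snp", "A1": "effect_allele", "A2": "other_allele",
            "BETA": "weight", "P": "p"})[
            ["snp", "effect_allele", "other_allele", "weight", "p"]])
        ped = simulate_pedigree(CohortDesign(n_families=10), seed=3)
        geno = simulate_target_genotypes(ped, gwas, seed=4)
        prof = threshold_and_score(ss, geno)
        counts = [prof.n_snps_used[p] for p in (0.01, 0.05, 0.1, 0.5)]
        assert counts == sorted(counts)
        sets = [set(prof.snps_used[p]) for p in (0.01, 0.05, 0.1, 0.5)]
        assert sets[0] <= sets[1] <= sets[2] <= sets[3]
        for p in prof.standardized:
            assert prof.standardized[p].mean() == pytest.approx(0.0, abs=1e-6)
            assert prof.standardized[p].std() == pytest.approx(1.0, abs=1e-5)


class TestAncestry:
    def test_two_populations_separate(self):
        rng = np.random.default_rng(9)
        n, m = 120, 300
        f1 = rng.uniform(0.1, 0.9, m)
        f2 = np.clip(f1 + rng.choice([-0.3, 0.3], m), 0.05, 0.95)
        pop = np.repeat([0, 1], n // 2)
        freqs = np.where(pop[:, None] == 0, f1, f2)
        g = _geno([f"rs{j}" for j in range(m)], ["A"] * m, ["G"] * m,
                  rng.binomial(2, freqs).astype(np.float32))
        comps = ancestry_components(g, k=2)
        r = np.corrcoef(comps[:, 0], pop)[0, 1]
        assert abs(r) > 0.9

    def test_k_zero_empty(self, trio):
        geno = simulate_target_genotypes(trio, GwasTruth(n_snps=10, n_causal=0), seed=1)
        assert ancestry_components(geno, k=0).shape == (3, 0)

    def test_k_exceeds_rank(self, trio):
        geno = simulate_target_genotypes(trio, GwasTruth(n_snps=10, n_causal=0), seed=1)
        with pytest.raises(ValueError, match="rank|variable"):
            ancestry_components(geno, k=5)

    def test_homogeneous_population_no_structure(self):
        rng = np.random.default_rng(10)
        n, m = 100, 400
        f = rng.uniform(0.2, 0.8, m)
        g = _geno([f"rs{j}" for j in range(m)], ["A"] * m, ["G"] * m,
                  rng.binomial(2, f, size=(n, m)).astype(np.float32))
        comps = ancestry_components(g, k=1)
        split = np.arange(n) < n // 2  # arbitrary grouping
        from scipy.stats import ttest_ind

        p = ttest_ind(comps[split, 0], comps[~split, 0]).pvalue
        assert p > 0.01


class TestAssociation:
    def test_variance_explained_formula(self):
        score = np.array([1.0, -1.0, 1.0, -1.0])  # variance 1
        assert prs_variance_explained(score, 0.1, np.full(4, 2.0) * [0, 1, 2, 3]) \
            == pytest.approx(0.1**2 * 1.0 / np.var([0.0, 2.0, 4.0, 6.0]))
        assert prs_variance_explained(score, 0.0, np.array([1.0, 2.0])) == 0.0

    def test_zero_phenotype_variance(self):
        with pytest.raises(ValueError, match="zero variance"):
            prs_variance_explained(np.array([1.0, -1.0]), 0.1, np.ones(5))

    def test_null_score_not_associated(self, small_cohort):
        from pedmix.prs import PRSProfile

        rng = np.random.default_rng(12)
        ids = tuple(small_cohort["pedigree"].ids)
        score = rng.standard_normal(len(ids))
        score = (score - score.mean()) / score.std()
        prof = PRSProfile(ids=ids, thresholds=(0.5,), n_snps_used={0.5: 100},
                          raw={0.5: score}, standardized={0.5: score})
        res = prs_mixed_association(
            prof, 0.5, small_cohort["phenotypes"], "cpg",
            structures={"additive": small_cohort["structures"]["additive"]},
        )
        assert abs(res.beta) < 4 * (res.interval[1] - res.beta) / 1.96
        assert res.backend == "reml"


class TestLDPruning:
    def test_greedy_window_pruning(self):
        rng = np.random.default_rng(21)
        n = 80
        base = rng.binomial(2, 0.4, size=(n, 1)).astype(np.float32)
        # SNPs 0 and 1 nearly identical; SNP 2 independent
        dup = base.copy()
        flip = rng.random((n, 1)) < 0.02
        dup[flip] = 2 - dup[flip]
        indep = rng.binomial(2, 0.4, size=(n, 1)).astype(np.float32)
        from pedmix.prs import prune_by_ld

        g = _geno(["rs0", "rs1", "rs2"], ["A"] * 3, ["G"] * 3,
                  np.hstack([base, dup, indep]))
        kept = prune_by_ld(g, p_values={"rs0": 1e-4, "rs1": 0.5, "rs2": 0.9},
                           r2_threshold=0.2)
        assert "rs0" in kept and "rs2" in kept and "rs1" not in kept
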