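import numpy as np
import pytest

from landgen.popgen import (
    MISSING,
    GenotypeFormatError,
    allele_counts,
    filter_maf,
    filter_missing,
    folded_sfs,
    impute_mode,
    load_genotypes,
    nucleotide_diversity,
    observed_heterozygosity,
    pairwise_fst,
)

from _oracles import fst_anova_oracle, pi_pairwise_oracle
from conftest import genotypes, hwe_genotypes


class TestLoading:
    def test_vcf_gt_codes(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1,length=100>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "1\t1\tL1\tA\tT\t.\tPASS\t.\tGT\t0/1\t./.\n"
            "1\t2\tL2\tA\tT\t.\tPASS\t.\tGT\t1/1\t0/0\n"
            "1\t3\tL3\tA\tT,G\t.\tPASS\t.\tGT\t0/1\t0/0\n"  # multiallelic: skipped
        )
        g = load_genotypes(vcf, format="vcf")
        assert g.locus_ids == ["1:1", "1:2"]
        assert g.calls.tolist() == [[1, 2], [MISSING, 0]]

    def test_csv_codes_and_na(self, tmp_path):
        csv = tmp_path / "g.csv"
        csv.write_text(
            "individual_id,population_label,L1,L2\nI1,P1,2,NA\nI2,P2,0,1\n"
        )
        g = load_genotypes(csv, format="csv")
        assert g.population_labels == ["P1", "P2"]
        assert g.calls.tolist() == [[2, MISSING], [0, 1]]

    def test_unparsable_vcf_is_format_error(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        )
        with pytest.raises(GenotypeFormatError):
            load_genotypes(vcf, format="vcf")

    def test_bad_csv_cell_rejected(self, tmp_path):
        csv = tmp_path / "g.csv"
        csv.write_text("individual_id,population_label,L1\nI1,P1,7\n")
        with pytest.raises(GenotypeFormatError, match="L1"):
            load_genotypes(csv, format="csv")


class TestFilters:
    def test_maf_removes_rare_and_folds(self):
        # 50 individuals -> 100 alleles; locus A: 4 alt (freq .04), locus B:
        # 96 alt (minor .04), locus C: monomorphic, locus D: freq .5
        n = 50
        a = np.zeros(n); a[:4] = 1
        b = np.full(n, 2.0); b[:4] = 1
        c = np.zeros(n)
        d = np.concatenate([np.zeros(n // 2), np.full(n // 2, 2.0)])
        g = genotypes(np.column_stack([a, b, c, d]))
        kept = filter_maf(g, 0.05)
        assert kept.locus_ids == ["L3"]  # only the freq-0.5 locus survives

    def test_missingness_boundary_locus_retained(self):
        n = 100
        col_31 = np.zeros(n); col_31[:31] = MISSING
        col_30 = np.zeros(n); col_30[:30] = MISSING
        col_0 = np.ones(n)
        g = genotypes(np.column_stack([col_31, col_30, col_0]))
        kept = filter_missing(g, 0.30)
        assert kept.locus_ids == ["L1", "L2"]

    def test_filters_commute_without_imputation(self):
        rng = np.random.default_rng(11)
        calls = rng.integers(0, 3, size=(40, 60)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.2] = MISSING
        g = genotypes(calls)
        ab = filter_missing(filter_maf(g, 0.1), 0.15)
        ba = filter_maf(filter_missing(g, 0.15), 0.1)
        assert ab.locus_ids == ba.locus_ids

    def test_impute_mode_examples(self):
        g = genotypes([[0], [0], [1], [MISSING]])
        assert impute_mode(g).calls[3, 0] == 0
        # tie between 0 and 1 -> smaller code
        g = genotypes([[0], [1], [MISSING]])
        assert impute_mode(g).calls[2, 0] == 0
        # no missing -> identity
        g = genotypes([[0, 2], [1, 1]])
        assert np.array_equal(impute_mode(g).calls, g.calls)

    def test_impute_population_scope_with_global_fallback(self, caplog):
        calls = [[2, MISSING], [2, MISSING], [0, 1], [MISSING, 1]]
        g = genotypes(calls, pops=["A", "A", "B", "B"])
        with caplog.at_level("WARNING"):
            out = impute_mode(g, scope="population")
        assert out.calls[0, 1] == 1  # pop A all-missing -> global mode
        assert out.calls[3, 0] == 0  # pop B mode
        assert (out.calls != MISSING).all()

    def test_impute_all_missing_locus_errors(self):
        g = genotypes([[MISSING], [MISSING]])
        with pytest.raises(ValueError, match="every individual"):
            impute_mode(g)


class TestFst:
    def test_matches_anova_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            freqs = rng.uniform(0.05, 0.95, size=(2, 5))
            g = hwe_genotypes(rng, freqs, n_per_pop=12, pops=["A", "B"])
            got = pairwise_fst(g, "A", "B")
            oracle = fst_anova_oracle(g.calls, g.population_labels, "A", "B")
            assert got == pytest.approx(oracle, abs=1e-10)

    def test_null_simulation_near_zero(self):
        rng = np.random.default_rng(22)
        base = rng.uniform(0.1, 0.9, size=1000)
        g = hwe_genotypes(rng, np.vstack([base, base]), n_per_pop=50, pops=["A", "B"])
        assert abs(pairwise_fst(g, "A", "B")) < 0.01

    def test_fixed_differences_approach_one(self):
        n = 20
        calls = np.vstack([np.zeros((n, 30)), np.full((n, 30), 2)])
        g = genotypes(calls, pops=["A"] * n + ["B"] * n)
        assert pairwise_fst(g, "A", "B") == pytest.approx(1.0, abs=1.0 / (2 * n - 1))

    def test_self_split_centered_on_zero(self):
        rng = np.random.default_rng(23)
        freqs = rng.uniform(0.2, 0.8, size=500)
        g = hwe_genotypes(rng, np.vstack([freqs, freqs]), n_per_pop=100, pops=["A", "B"])
        assert abs(pairwise_fst(g, "A", "B")) < 0.005

    def test_needs_two_individuals(self):
        g = genotypes([[1], [0]], pops=["A", "B"])
        with pytest.raises(ValueError, match=">= 2"):
            pairwise_fst(g, "A", "B")


class TestDiversity:
    def test_monomorphic_population_zero(self):
        g = genotypes([[0, 0], [0, 0]])
        assert nucleotide_diversity(g, "P1", 2) == 0.0

    def test_single_het_individual(self):
        # one diploid with one of each allele: two alleles always mismatch
        g = genotypes([[1]])
        assert nucleotide_diversity(g, "P1", 1) == pytest.approx(1.0)

    def test_matches_pairwise_mismatch_oracle(self):
        rng = np.random.default_rng(31)
        calls = rng.integers(0, 3, size=(5, 10)).astype(np.int8)
        g = genotypes(calls)
        got = nucleotide_diversity(g, "P1", 25)
        oracle = pi_pairwise_oracle(g.calls, g.population_labels, "P1", 25)
        assert got == pytest.approx(oracle, abs=1e-10)

    def test_monomorphic_sites_dilute_denominator(self):
        g = genotypes([[1], [1]])
        assert nucleotide_diversity(g, "P1", 10) == pytest.approx(
            nucleotide_diversity(g, "P1", 1) / 10
        )

    def test_allele_label_swap_invariance(self):
        rng = np.random.default_rng(32)
        calls = rng.integers(0, 3, size=(8, 20)).astype(np.int8)
        g = genotypes(calls)
        swapped = genotypes(2 - calls)
        assert nucleotide_diversity(g, "P1", 20) == pytest.approx(
            nucleotide_diversity(swapped, "P1", 20), abs=1e-12
        )
        assert observed_heterozygosity(g, "P1", 20) == pytest.approx(
            observed_heterozygosity(swapped, "P1", 20), abs=1e-12
        )


class TestHeterozygosity:
    def test_extremes(self):
        assert observed_heterozygosity(genotypes([[0, 2], [2, 0]]), "P1", 2) == 0.0
        assert observed_heterozygosity(genotypes([[1, 1], [1, 1]]), "P1", 2) == 1.0

    def test_direct_count(self):
        g = genotypes([[1, 0, 1], [0, 0, 1], [2, 1, MISSING]])
        # per-locus het fractions: 1/3, 1/3, 2/2 -> sum / total_sites
        assert observed_heterozygosity(g, "P1", 3) == pytest.approx((1 / 3 + 1 / 3 + 1.0) / 3)


class TestFoldedSfs:
    def test_minor_allele_binning_and_folding(self):
        calls = np.zeros((12, 2), dtype=np.int8)
        calls[0, 0] = 2
        calls[1, 0] = 1       # locus 1: alt count 3 of 24
        calls[:10, 1] = 2
        calls[10, 1] = 1      # locus 2: alt count 21 of 24 -> folds to 3
        g = genotypes(calls)
        sfs = folded_sfs(g, "P1")
        assert sfs.allele_number == 24
        assert sfs.bins[3] == 2
        assert sfs.bins.sum() == 2
        assert all(sfs.bins[k] == 0 for k in range(13, 25))

    def test_bins_conserve_locus_count_and_label_swap(self):
        rng = np.random.default_rng(41)
        calls = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
        g = genotypes(calls)
        sfs = folded_sfs(g, "P1")
        assert sfs.bins.sum() == 50
        swapped = folded_sfs(genotypes(2 - calls), "P1")
        assert np.array_equal(sfs.bins, swapped.bins)

    def test_missing_calls_rejected(self):
        g = genotypes([[1, MISSING], [0, 1]])
        with pytest.raises(ValueError, match="impute"):
            folded_sfs(g, "P1")


class TestAlleleCounts:
    def test_tally_skips_missing(self):
        g = genotypes([[2, 1], [MISSING, 0]], pops=["A", "A"])
        t = allele_counts(g)
        assert t.alt_count.tolist() == [[2, 1]]
        assert t.allele_number.tolist() == [[2, 4]]
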