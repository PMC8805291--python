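"""Genotype I/O, quality filters, LD pruning and F_ST."""

import numpy as np
import pandas as pd
import pytest

from troutscan import genotypes as gt
from troutscan.genotypes import MISSING, GenotypeError

from conftest import make_matrix, hwe_matrix, simple_meta


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
    "##contig=<ID=chr1>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsA\tsB\tsC\n"
)


def _write_vcf(tmp_path, body):
    path = tmp_path / "test.vcf"
    path.write_text(VCF_HEADER + body)
    return str(path)


class TestReadVcf:
    def test_empty_vcf_keeps_samples(self, tmp_path):
        G = gt.read_vcf(_write_vcf(tmp_path, ""))
        assert G.sample_ids == ["sA", "sB", "sC"]
        assert G.n_snps == 0

    def test_direct_genotype_encoding(self, tmp_path):
        body = (
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:DP\t0/0:10\t0/1:12\t1/1:9\n"
            "chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT:DP\t./.:0\t0/0:8\t0/1:7\n"
        )
        G = gt.read_vcf(_write_vcf(tmp_path, body))
        assert G.calls[:, 0].tolist() == [0, 1, 2]
        assert G.calls[:, 1].tolist() == [MISSING, 0, 1]
        assert G.depth[:, 0].tolist() == [10, 12, 9]

    def test_non_biallelic_sites_skipped(self, tmp_path):
        rows = [
            f"chr1\t{100 * (i + 1)}\t.\tA\tG\t.\tPASS\t.\tGT:DP\t0/0:9\t0/1:9\t1/1:9"
            for i in range(4)
        ]
        rows.insert(2, "chr1\t250\t.\tA\tG,T\t.\tPASS\t.\tGT:DP\t0/0:9\t0/1:9\t1/2:9")
        G = gt.read_vcf(_write_vcf(tmp_path, "\n".join(rows) + "\n"))
        assert G.n_snps == 4
        assert 250 not in G.snps["pos"].tolist()

    def test_write_read_roundtrip(self, tmp_path, rng):
        calls = rng.integers(-1, 3, size=(5, 12))
        depth = rng.integers(0, 40, size=(5, 12))
        G = make_matrix(calls, depth=depth)
        path = tmp_path / "rt.vcf"
        gt.write_vcf(G, path)
        G2 = gt.read_vcf(str(path))
        np.testing.assert_array_equal(G.calls, G2.calls)
        np.testing.assert_array_equal(G.depth, G2.depth)
        assert G.sample_ids == G2.sample_ids
        pd.testing.assert_frame_equal(G.snps, G2.snps)


# ---------------------------------------------------------------------------
# Sample / entry coverage filters
# ---------------------------------------------------------------------------

class TestCoverageFilters:
    def test_mean_coverage_boundary_is_strict(self):
        G = make_matrix([[0, 1], [1, 2], [0, 0]])
        meta = simple_meta(G, coverages=[4.9, 5.0, 20.0])
        G2, meta2 = gt.drop_low_coverage_samples(G, meta, min_mean=5)
        assert G2.sample_ids == ["s01", "s02"]
        assert [m.sample_id for m in meta2] == ["s01", "s02"]

    def test_all_above_threshold_is_noop(self):
        G = make_matrix([[0, 1], [1, 2]])
        G2, _ = gt.drop_low_coverage_samples(G, simple_meta(G, [5.0, 9.0]))
        assert G2.sample_ids == G.sample_ids

    def test_all_below_threshold_fatal(self):
        G = make_matrix([[0, 1]])
        with pytest.raises(GenotypeError):
            gt.drop_low_coverage_samples(G, simple_meta(G, [1.0]))

    def test_mask_depth_boundary(self):
        G = make_matrix([[1, 1, 1]], depth=[[4, 5, 100]])
        G2 = gt.mask_low_coverage(G, min_depth=5)
        assert G2.calls[0].tolist() == [MISSING, 1, 1]
        # depth retained for audit
        assert G2.depth[0].tolist() == [4, 5, 100]

    def test_mask_noop_at_high_depth(self):
        G = make_matrix([[0, 1], [2, 1]], depth=[[100, 100], [100, 100]])
        np.testing.assert_array_equal(gt.mask_low_coverage(G).calls, G.calls)


# ---------------------------------------------------------------------------
# SNP-level filters
# ---------------------------------------------------------------------------

class TestSnpFilters:
    def test_missingness_boundary_inclusive(self):
        # SNP0 informative in 49/100 -> removed; SNP1 in 50/100 -> kept
        calls = np.zeros((100, 2), dtype=np.int8)
        calls[49:, 0] = MISSING
        calls[50:, 1] = MISSING
        G2 = gt.filter_missingness(make_matrix(calls), 0.5)
        assert G2.snps["pos"].tolist() == [200]

    def test_missingness_noop_when_fully_typed(self):
        G = make_matrix([[0, 1], [1, 2]])
        assert gt.filter_missingness(G).n_snps == 2

    def test_missingness_all_removed_fatal(self):
        calls = np.full((10, 2), MISSING, dtype=np.int8)
        with pytest.raises(GenotypeError):
            gt.filter_missingness(make_matrix(calls))

    def test_excess_het_boundary_strict(self):
        # SNP0: 81/100 hets -> removed; SNP1: 80/100 -> kept; SNP2 monomorphic
        calls = np.zeros((100, 3), dtype=np.int8)
        calls[:81, 0] = 1
        calls[:80, 1] = 1
        G2 = gt.filter_excess_het(make_matrix(calls), 0.8)
        assert G2.snps["pos"].tolist() == [200, 300]

    def test_maf_boundary(self):
        # SNP0: MAF 0.04 (4 alt alleles in 50 individuals = 100 alleles)
        calls = np.zeros((50, 2), dtype=np.int8)
        calls[:4, 0] = 1  # freq 0.04
        calls[:30, 1] = 1  # freq 0.30
        G2 = gt.filter_maf(make_matrix(calls), 0.05)
        assert G2.snps["pos"].tolist() == [200]

    def test_maf_zero_removes_only_monomorphic(self):
        calls = np.array([[0, 1, 2], [0, 1, 0], [0, 0, 1]], dtype=np.int8)
        G2 = gt.filter_maf(make_matrix(calls), 0.0)
        assert G2.snps["pos"].tolist() == [200, 300]

    def test_maf_hand_counted_survivors(self):
        # 10 SNPs in 10 samples; alt-allele counts 0..9 of 20 -> freqs 0..0.45
        calls = np.zeros((10, 10), dtype=np.int8)
        for j in range(10):
            calls[: j // 2, j] = 2
            if j % 2:
                calls[j // 2, j] = 1
        freqs = calls.sum(axis=0) / 20
        survivors = [100 * (j + 1) for j in range(10) if min(freqs[j], 1 - freqs[j]) > 0.2]
        G2 = gt.filter_maf(make_matrix(calls), 0.2)
        assert G2.snps["pos"].tolist() == survivors

    @pytest.mark.parametrize(
        "filt",
        [
            lambda G: gt.mask_low_coverage(G, 5),
            lambda G: gt.filter_missingness(G, 0.5),
            lambda G: gt.filter_excess_het(G, 0.8),
            lambda G: gt.filter_maf(G, 0.1),
        ],
    )
    def test_filters_idempotent(self, filt, rng):
        calls = rng.integers(-1, 3, size=(30, 40))
        depth = rng.integers(0, 30, size=(30, 40))
        G = make_matrix(calls, depth=depth)
        once = filt(G)
        twice = filt(once)
        np.testing.assert_array_equal(once.calls, twice.calls)
        pd.testing.assert_frame_equal(once.snps, twice.snps)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _brute_force_max_r2(G):
    """Exhaustive all-pairs composite r^2 within each chromosome (oracle)."""
    worst = 0.0
    for chrom in G.snps["chrom"].unique():
        idx = np.flatnonzero(G.snps["chrom"].to_numpy() == chrom)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                r2 = gt.pairwise_r2(G.calls[:, idx[a]], G.calls[:, idx[b]])
                worst = max(worst, r2)
    return worst


class TestLdPrune:
    def test_duplicated_columns_keep_one(self, rng):
        col = rng.integers(0, 3, size=20)
        G = make_matrix(np.stack([col, col], axis=1))
        assert gt.ld_prune(G, 0.2).n_snps == 1

    def test_independent_snps_both_survive(self, rng):
        calls = rng.binomial(2, 0.5, size=(200, 2))
        G = make_matrix(calls)
        assert gt.ld_prune(G, 0.2).n_snps == 2

    def test_output_passes_exhaustive_pairwise_oracle(self, rng):
        base = rng.binomial(2, 0.4, size=(60, 20)).astype(np.int8)
        # plant correlated columns
        for j in range(0, 20, 4):
            base[:, j + 1] = base[:, j]
            flip = rng.random(60) < 0.1
            base[flip, j + 1] = rng.integers(0, 3, size=int(flip.sum()))
        pruned = gt.ld_prune(make_matrix(base), 0.2)
        assert pruned.n_snps < 20
        assert _brute_force_max_r2(pruned) <= 0.2


# ---------------------------------------------------------------------------
# F_ST and diagnostic SNPs
# ---------------------------------------------------------------------------

class TestFst:
    def test_identical_frequencies_near_zero(self, rng):
        freqs = rng.uniform(0.2, 0.8, 50)
        calls = np.concatenate(
            [rng.binomial(2, freqs, (100, 50)), rng.binomial(2, freqs, (100, 50))]
        )
        track = gt.per_snp_fst(
            make_matrix(calls), {"a": np.arange(100), "b": np.arange(100, 200)}
        )
        assert abs(np.nanmean(track["value"])) < 0.02

    def test_fixed_difference_is_one(self):
        calls = np.array([[0, 0], [0, 0], [2, 2], [2, 2]], dtype=np.int8)
        track = gt.per_snp_fst(make_matrix(calls), {"a": [0, 1], "b": [2, 3]})
        np.testing.assert_allclose(track["value"], 1.0)

    def test_hudson_formula_oracle(self):
        # pop1: 50 individuals at p = 0.2 (10 het + 5 hom-alt);
        # pop2: 50 individuals at p = 0.8 (mirror)
        pop1 = np.zeros((50, 1), dtype=np.int8)
        pop1[:10] = 1
        pop1[10:15] = 2
        pop2 = 2 - pop1
        calls = np.concatenate([pop1, pop2])
        track = gt.per_snp_fst(make_matrix(calls), {"a": np.arange(50), "b": np.arange(50, 100)})
        # textbook Hudson estimator, worked by hand with allele counts n = 100
        p1, p2, n1, n2 = 0.2, 0.8, 100, 100
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        np.testing.assert_allclose(track["value"].iloc[0], num / den, rtol=1e-12)

    def test_population_missing_everywhere_gives_na(self):
        calls = np.array([[0], [2], [MISSING], [MISSING]], dtype=np.int8)
        track = gt.per_snp_fst(make_matrix(calls), {"a": [0, 1], "b": [2, 3]})
        assert np.isnan(track["value"].iloc[0])


class TestDiagnosticSnps:
    def test_no_snp_above_threshold(self):
        calls = np.array([[0, 1], [1, 0], [0, 1], [1, 0]], dtype=np.int8)
        G = make_matrix(calls)
        track = gt.per_snp_fst(G, {"a": [0, 1], "b": [2, 3]})
        assert len(gt.select_diagnostic_snps(track, G)) == 0

    def test_high_ld_diagnostic_pair_collapsed(self):
        # 5 fixed-difference SNPs; the two on chr1 are in perfect LD (pruning
        # acts within chromosomes), the rest sit on their own chromosomes
        pop1 = np.zeros((30, 5), dtype=np.int8)
        pop2 = np.full((30, 5), 2, dtype=np.int8)
        calls = np.concatenate([pop1, pop2])
        G = make_matrix(calls, chrom=["c1", "c1", "c2", "c3", "c4"])
        track = gt.per_snp_fst(G, {"a": np.arange(30), "b": np.arange(30, 60)})
        chosen = gt.select_diagnostic_snps(track, G, fst_min=0.95, r2_max=0.2)
        assert len(chosen) == 4
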