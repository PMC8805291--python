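"""Windowed ZHp scan, SNP p-value runs, IBD-kinship scan, permutation nulls."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from troutscan import scan, simulate as sim
from troutscan.genotypes import GenotypeError

from conftest import make_matrix


def track_from_values(values, window=2_000_000, step=1_000_000, chrom_len=None):
    """One-chromosome window track with the given statistic values."""
    n = len(values)
    if chrom_len is None:
        chrom_len = step * n
    scheme = scan.WindowScheme(window, step, {"chr1": chrom_len})
    win = scheme.windows("chr1")
    assert len(win) == n
    win["n_snps"] = 10
    win["value"] = np.asarray(values, dtype=float)
    return win


class TestWindowScheme:
    def test_tiling_covers_chromosome(self):
        s = scan.WindowScheme(1_000_000, 200_000, {"chr1": 3_500_000})
        win = s.windows("chr1")
        assert win["start"].iloc[0] == 1
        assert win["end"].iloc[-1] == 3_500_001
        # consecutive starts step by 200 kb, ends clipped to chromosome end
        assert (np.diff(win["start"]) == 200_000).all()
        assert (win["end"] - win["start"] <= 1_000_000).all()

    def test_step_above_window_rejected(self):
        with pytest.raises(GenotypeError):
            scan.WindowScheme(100, 200, {"chr1": 1000})


class TestPooledHet:
    def test_hand_computed_hp(self):
        # one window, 2 SNPs with pool (maj, min) counts (8,2) and (6,4):
        # Hp = 2*14*6/20^2 = 0.42
        calls = np.array(
            [[2, 2], [0, 2], [0, 0], [0, 0], [0, 0]], dtype=np.int8
        )
        G = make_matrix(calls, positions=[100, 200])
        scheme = scan.WindowScheme(1000, 1000, {"chr1": 1000})
        hp = scan.pooled_het_track(G, np.arange(5), scheme)
        assert hp["value"].iloc[0] == pytest.approx(0.42)
        assert hp["n_snps"].iloc[0] == 2

    def test_fixed_pool_hp_zero(self):
        G = make_matrix(np.zeros((4, 3), dtype=np.int8), positions=[10, 20, 30])
        scheme = scan.WindowScheme(1000, 1000, {"chr1": 1000})
        assert scan.pooled_het_track(G, np.arange(4), scheme)["value"].iloc[0] == 0.0

    def test_balanced_pool_hp_maximal(self):
        calls = np.array([[0, 0], [0, 0], [2, 2], [2, 2]], dtype=np.int8)
        G = make_matrix(calls, positions=[10, 20])
        scheme = scan.WindowScheme(1000, 1000, {"chr1": 1000})
        assert scan.pooled_het_track(G, np.arange(4), scheme)["value"].iloc[0] == 0.5

    def test_empty_window_is_na(self):
        G = make_matrix(np.array([[0, 2]], dtype=np.int8), positions=[100, 150])
        scheme = scan.WindowScheme(1000, 1000, {"chr1": 2000})
        hp = scan.pooled_het_track(G, np.arange(1), scheme)
        assert np.isnan(hp["value"].iloc[1])


class TestZhpTrack:
    def test_three_value_standardization(self):
        z = scan.zhp_track(track_from_values([0.1, 0.2, 0.3]))
        np.testing.assert_allclose(z["value"], [-1.22474487, 0, 1.22474487], atol=1e-12)

    def test_constant_track_fatal(self):
        with pytest.raises(GenotypeError):
            scan.zhp_track(track_from_values([0.2, 0.2, 0.2]))

    def test_output_exactly_standardized(self, rng):
        vals = rng.uniform(0.1, 0.4, 50)
        vals[7] = np.nan
        z = scan.zhp_track(track_from_values(vals, chrom_len=50_000_000))
        ok = z["value"].dropna()
        assert abs(ok.mean()) < 1e-12
        assert abs(ok.std(ddof=0) - 1) < 1e-12


class TestSignificantWindows:
    def test_threshold_boundary_inclusive(self):
        flags = scan.directions_z(np.array([-2.80, -2.81, 2.81, 3.75, 0.0]))
        assert flags.tolist() == ["", "low", "high", "high", ""]

    def test_no_extreme_values_empty(self):
        out = scan.significant_windows(track_from_values([0.5, -1.9, 1.2]))
        assert out.empty

    def test_kinship_boundary_inclusive(self):
        assert scan.directions_ge(np.array([0.05]))[0] == "high"
        assert scan.directions_ge(np.array([0.0499]))[0] == ""


class TestMergeRegions:
    def test_empty_input(self):
        assert scan.merge_regions(pd.DataFrame(columns=["chrom", "start", "end", "value", "direction"])).empty

    def test_two_overlapping_windows_one_region(self):
        # 1 Mb windows, 200 kb step: two adjacent flagged windows span 1.2 Mb
        flagged = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [1, 200_001],
                "end": [1_000_001, 1_200_001],
                "value": [-3.0, -3.2],
                "direction": ["low", "low"],
            }
        )
        regs = scan.merge_regions(flagged)
        assert len(regs) == 1
        assert regs["end"].iloc[0] - regs["start"].iloc[0] == 1_200_000
        assert regs["n_units"].iloc[0] == 2

    def test_isolated_window_no_region(self):
        flagged = pd.DataFrame(
            {"chrom": ["chr1"], "start": [1], "end": [1_000_001],
             "value": [-3.0], "direction": ["low"]}
        )
        assert scan.merge_regions(flagged).empty

    def test_directions_never_merged(self):
        flagged = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [1, 200_001],
                "end": [1_000_001, 1_200_001],
                "value": [-3.0, 3.2],
                "direction": ["low", "high"],
            }
        )
        assert scan.merge_regions(flagged).empty

    def test_invariant_to_row_order(self, rng):
        flagged = pd.DataFrame(
            {
                "chrom": ["chr2", "chr1", "chr1", "chr2"],
                "start": [400_001, 1, 200_001, 600_001],
                "end": [1_400_001, 1_000_001, 1_200_001, 1_600_001],
                "value": [-3.0, -3.0, -3.1, -3.3],
                "direction": ["low"] * 4,
            }
        )
        a = scan.merge_regions(flagged)
        b = scan.merge_regions(flagged.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(a, b)


def exhaustive_adjacency_p(n_windows, n_flagged, min_chain, reach):
    """P(some chain of >= min_chain mutually overlapping flagged windows).

    Exhaustive enumeration over all placements of the flagged slots; windows i
    and j overlap iff |i - j| <= reach.  Independent combinatorial oracle for
    the permutation null.
    """
    hits = total = 0
    for combo in combinations(range(n_windows), n_flagged):
        total += 1
        chain = 1
        best = 1
        for a, b in zip(combo, combo[1:]):
            chain = chain + 1 if b - a <= reach else 1
            best = max(best, chain)
        if best >= min_chain:
            hits += 1
    return hits / total


class TestResampleWindowNull:
    def test_no_significant_windows_no_regions(self, rng):
        track = track_from_values(rng.normal(0, 0.5, 20), chrom_len=20_000_000)
        out = scan.resample_window_null(track, scan.directions_z, 50, seed=1)
        assert out.empty

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        # 10 windows (2 Mb / 1 Mb: reach 1), 2 flagged "low": a region occurs
        # iff the two flagged slots are adjacent -> p = 9 / C(10,2) = 0.2
        vals = np.zeros(10)
        vals[3], vals[4] = -3.0, -3.1
        track = track_from_values(vals)
        out = scan.resample_window_null(track, scan.directions_z, 1000, seed=7)
        assert len(out) == 1
        p_exact = exhaustive_adjacency_p(10, 2, 2, reach=1)
        assert p_exact == pytest.approx(0.2)
        se = np.sqrt(p_exact * (1 - p_exact) / 1000)
        assert abs(out["empirical_p"].iloc[0] - p_exact) <= 3 * se + 1e-3

    def test_plus_one_rule_floor(self):
        # 8 flagged of 10 windows: the observed chain is near-maximal but can
        # always be reproduced; with all windows flagged p must be 1
        vals = np.full(10, -5.0)
        track = track_from_values(vals)
        out = scan.resample_window_null(track, scan.directions_z, 99, seed=3)
        assert (out["empirical_p"] == 1.0).all()

    def test_reproducible_under_seed(self, rng):
        vals = rng.normal(0, 1.5, 30)
        track = track_from_values(vals, chrom_len=30_000_000)
        a = scan.resample_window_null(track, scan.directions_z, 200, seed=42)
        b = scan.resample_window_null(track, scan.directions_z, 200, seed=42)
        pd.testing.assert_frame_equal(a, b)


class TestSnpPRegions:
    def test_alternating_significance_no_region(self):
        track = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(1, 7) * 100,
             "p": [0.005, 0.5, 0.005, 0.5, 0.005, 0.5]}
        )
        assert scan.snp_p_regions(track, n_resamples=10, seed=1).empty

    def test_run_of_three_called(self):
        track = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(1, 6) * 100,
             "p": [0.9, 0.001, 0.001, 0.001, 0.9]}
        )
        regs = scan.snp_p_regions(track, n_resamples=100, seed=1)
        assert len(regs) == 1
        assert regs["n_units"].iloc[0] == 3
        assert regs["start"].iloc[0] == 200 and regs["end"].iloc[0] == 401

    def test_runs_do_not_cross_chromosomes(self):
        track = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr2", "chr2"],
             "pos": [100, 200, 100, 200],
             "p": [0.9, 0.001, 0.001, 0.9]}
        )
        assert scan.snp_p_regions(track, n_resamples=10, seed=1).empty

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        # 12 SNPs, 3 significant: exhaustive run-length probability
        p = np.full(12, 0.9)
        p[[2, 3, 8]] = 0.001
        track = pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, 13) * 100, "p": p})
        regs = scan.snp_p_regions(track, n_resamples=1000, seed=11)
        assert len(regs) == 1 and regs["n_units"].iloc[0] == 2
        p_exact = exhaustive_adjacency_p(12, 3, 2, reach=1)
        se = np.sqrt(p_exact * (1 - p_exact) / 1000)
        assert abs(regs["empirical_p"].iloc[0] - p_exact) <= 3 * se + 1e-3


@pytest.fixture(scope="module")
def shared_block_cohort():
    cfg = sim.SimConfig(
            seed=21, n_snps=12000,
        sweeps=[sim.SweepSpec("chr2", 7_500_001, 17_500_001, "ibd_share")],
    )
    co = sim.simulate_cohort(cfg)
    pops = {
        lab: np.array([i for i, m in enumerate(co.meta) if m.lineage == lab])
        for lab in ("AT", "CA", "MA", "MI", "MM")
    }
    scheme = scan.WindowScheme(5_000_000, 2_500_000, cfg.chrom_lengths)
    track, regions = scan.kinship_window_scan(
        co.genotypes, pops, scheme, n_resamples=200, seed=5
    )
    return track, regions


class TestKinshipWindowScan:

    def test_shared_haplotype_block_detected(self, shared_block_cohort):
        track, regions = shared_block_cohort
        inside = track[
            (track["chrom"] == "chr2")
            & (track["start"] >= 7_500_000)
            & (track["end"] <= 17_500_001)
        ]
        assert (inside["value"] >= 0.05).all()
        retained = regions[regions["retained"]]
        assert len(retained) >= 1
        assert retained["chrom"].iloc[0] == "chr2"

    def test_background_below_threshold(self, shared_block_cohort):
        track, _ = shared_block_cohort
        outside = track[track["chrom"] == "chr1"]["value"].dropna()
        assert (outside < 0.05).all()

    def test_fewer_than_two_populations_fatal(self):
        G = make_matrix(np.zeros((4, 3), dtype=np.int8))
        scheme = scan.WindowScheme(1000, 500, {"chr1": 1000})
        with pytest.raises(GenotypeError):
            scan.kinship_window_scan(G, {"a": np.arange(4)}, scheme)


class TestOverlapRegions:
    def _reg(self, chrom, start, end):
        return pd.DataFrame({"chrom": [chrom], "start": [start], "end": [end]})

    def test_disjoint_empty(self):
        assert scan.overlap_regions(self._reg("chr1", 1, 10), self._reg("chr1", 20, 30)).empty

    def test_identical_full_overlap(self):
        out = scan.overlap_regions(self._reg("chr1", 1, 100), self._reg("chr1", 1, 100))
        assert out["overlap_bp"].iloc[0] == 99

    def test_partial_interval_arithmetic(self):
        out = scan.overlap_regions(
            self._reg("chr1", 1_000_000, 3_000_000), self._reg("chr1", 2_000_000, 5_000_000)
        )
        assert out["overlap_bp"].iloc[0] == 1_000_000


class TestStratifiedScan:
    def test_all_stratum_equals_unstratified(self, rng):
        vals = rng.normal(0, 1.5, 30)
        track = track_from_values(vals, chrom_len=30_000_000)
        base = scan.resample_window_null(track, scan.directions_z, 100, seed=2)

        def fn(idx):
            return scan.resample_window_null(track, scan.directions_z, 100, seed=2)

        results, annotated = scan.stratified_scan(fn, {"all": np.arange(20)}, base)
        pd.testing.assert_frame_equal(results["all"], base)

    def test_small_stratum_skipped(self):
        def fn(idx):
            raise AssertionError("must not run")

        results, _ = scan.stratified_scan(fn, {"tiny": np.arange(2)}, None)
        assert results == {}

    def test_private_sweep_found_only_in_affected_lineage(self):
        cfg = sim.SimConfig(
            seed=31, n_snps=9000,
            chrom_lengths={"chr1": 20_000_000, "chr2": 20_000_000, "chr3": 20_000_000},
            pop_sizes={"MA": 20, "CA": 20},
            pop_fst={"MA": 0.25, "CA": 0.25},
            origins={"MA": (20, 0, 0), "CA": (17, 0, 3)},
            admixture=[],
            sweeps=[sim.SweepSpec("chr1", 8_000_001, 11_000_001, "low_het",
                                  pops=("MA",), intensity=0.95)],
        )
        co = sim.simulate_cohort(cfg)
        scheme = scan.WindowScheme(1_000_000, 200_000, cfg.chrom_lengths)
        idx = {
            lab: np.array([i for i, m in enumerate(co.meta) if m.lineage == lab])
            for lab in ("MA", "CA")
        }
        _, ma_regions = scan.zhp_scan(co.genotypes, idx["MA"], scheme, seed=3, n_resamples=200)
        _, ca_regions = scan.zhp_scan(co.genotypes, idx["CA"], scheme, seed=3, n_resamples=200)
        ma_low = ma_regions[(ma_regions["direction"] == "low") & ma_regions["retained"]]
        assert len(ma_low) == 1
        assert ma_low["start"].iloc[0] < 11_000_001 and ma_low["end"].iloc[0] > 8_000_000
        assert ca_regions[
            (ca_regions["direction"] == "low")
            & (ca_regions["start"] < 11_000_001)
            & (ca_regions["end"] > 8_000_000)
            & ca_regions["retained"]
        ].empty


class TestDirectionConsistency:
    def test_low_regions_have_low_hp(self):
        cfg = sim.SimConfig(
            seed=41, n_snps=8000,
            chrom_lengths={"chr1": 20_000_000, "chr2": 20_000_000},
            sweeps=[sim.SweepSpec("chr1", 5_000_001, 7_000_001, "low_het", intensity=0.9)],
        )
        co = sim.simulate_cohort(cfg)
        scheme = scan.WindowScheme(1_000_000, 200_000, cfg.chrom_lengths)
        hp = scan.pooled_het_track(co.genotypes, np.arange(co.genotypes.n_samples), scheme)
        z = scan.zhp_track(hp)
        regs = scan.resample_window_null(z, scan.directions_z, 100, seed=1)
        low = regs[regs["direction"] == "low"]
        assert len(low) >= 1
        genome_mean = hp["value"].mean()
        for _, reg in low.iterrows():
            inside = hp[
                (hp["chrom"] == reg["chrom"])
                & (hp["start"] >= reg["start"])
                & (hp["end"] <= reg["end"])
            ]["value"].mean()
            assert inside < genome_mean
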