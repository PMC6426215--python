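"""Bin-map construction: QC statistics against brute-force recounts,
strict filter thresholds, orientation-free similarity, window linkage
screening, greedy bin merging against a pattern-hash oracle, and Haldane
distance estimation."""

import numpy as np
import pandas as pd
import pytest

from pgebv.core import GenotypeMatrix, PARENT_A, PARENT_B, HET, MISSING
from pgebv import binmap as bm
from pgebv.simulate import default_map, simulate_dh_genotypes, apply_gbs_noise

A, B, H, M = int(PARENT_A), int(PARENT_B), int(HET), int(MISSING)


def _geno(calls, positions=None, chrom="c1"):
    calls = np.asarray(calls, dtype=np.int8)
    n_lines, n_snps = calls.shape
    pos = positions if positions is not None else np.arange(n_snps, dtype=float)
    mm = pd.DataFrame({"marker": [f"m{j}" for j in range(n_snps)],
                       "chrom": chrom, "pos_cM": pos})
    return GenotypeMatrix(calls, [f"L{i}" for i in range(n_lines)], mm)


class TestQcStats:
    def test_balanced_snp_maf_half(self):
        g = _geno(np.array([[A], [A], [B], [B]]))
        stats = bm.compute_qc_stats(g)
        assert stats.maf[0] == pytest.approx(0.5)

    def test_missing_and_monomorphic(self):
        g = _geno(np.array([[A], [A], [A], [M]]))
        stats = bm.compute_qc_stats(g)
        assert stats.missing_rate_snp[0] == pytest.approx(0.25)
        assert stats.maf[0] == pytest.approx(0.0)

    def test_het_counts_half_per_allele(self):
        g = _geno(np.array([[A], [H], [B], [B]]))
        stats = bm.compute_qc_stats(g)
        assert stats.maf[0] == pytest.approx((1 + 0.5) / 4)

    def test_matches_bruteforce_recount(self, clean_geno):
        noisy = apply_gbs_noise(clean_geno, 0.1, 0.05, seed=8)
        stats = bm.compute_qc_stats(noisy)
        for j in [0, 57, 499, 999]:
            col = noisy.calls[:, j]
            n_a = int((col == A).sum())
            n_b = int((col == B).sum())
            n_h = int((col == H).sum())
            n_m = int((col == M).sum())
            called = n_a + n_b + n_h
            fb = (n_b + 0.5 * n_h) / called
            assert stats.maf[j] == pytest.approx(min(fb, 1 - fb))
            assert stats.missing_rate_snp[j] == pytest.approx(n_m / 97)
        for i in [0, 42, 96]:
            row = noisy.calls[i]
            n_m = int((row == M).sum())
            n_h = int((row == H).sum())
            assert stats.missing_rate_line[i] == pytest.approx(n_m / 1000)
            assert stats.het_rate_line[i] == pytest.approx(n_h / (1000 - n_m))


class TestFilters:
    def test_threshold_semantics_strict(self):
        # maf 0.04 removed; maf 0.06 & missing 0.1 retained
        n = 50
        low = np.full(n, A); low[:2] = B                    # maf 0.04
        ok = np.full(n, A); ok[:3] = B                      # maf 0.06
        ok_miss = ok.copy(); ok_miss[-5:] = M               # missing 0.10
        g = _geno(np.column_stack([low, ok, ok_miss]))
        out = bm.filter_snps(g)
        assert out.marker_ids == ["m1", "m2"]

    def test_null_thresholds_identity(self, clean_geno):
        out = bm.filter_snps(clean_geno, maf_min=0.0, missing_max=1.01)
        assert out.n_snps == clean_geno.n_snps

    def test_inclusion_exclusion_fixture(self):
        """1000 SNPs; 100 low-MAF, 50 high-missing, 10 overlapping -> 860."""
        rng = np.random.default_rng(0)
        n = 97
        calls = rng.choice(np.array([A, B], dtype=np.int8), size=(n, 1000))
        calls[: n // 2, :] = A  # keep genuine MAF high elsewhere
        calls[n // 2:, :] = B
        low_maf = np.arange(100)          # indices 0..99
        high_miss = np.arange(90, 140)    # overlap 90..99 (10 SNPs)
        for j in low_maf:
            calls[:, j] = A
            calls[:2, j] = B              # maf ~ 0.02 < 0.05
        for j in high_miss:
            calls[:20, j] = M             # missing 20/97 > 20%... and >= 0.20
        g = _geno(calls)
        out = bm.filter_snps(g)
        assert out.n_snps == 860

    def test_line_filter_strict_boundary(self):
        n_snps = 100
        rng = np.random.default_rng(1)
        base = rng.choice(np.array([A, B], dtype=np.int8), size=(4, n_snps))
        base[0, :6] = H    # 6% het -> removed
        base[1, :5] = H    # exactly 5% -> retained
        base[2, :21] = M   # 21% missing -> removed
        g = _geno(base)
        out = bm.filter_lines(g)
        assert out.line_ids == ["L1", "L3"]

    def test_clean_dh_lines_all_retained(self, clean_geno):
        out = bm.filter_lines(clean_geno)
        assert out.n_lines == clean_geno.n_lines

    def test_fixture_with_injected_het_lines(self, clean_geno):
        calls = clean_geno.calls.copy()
        for i in (3, 10, 42):
            calls[i, :100] = H  # 10% het
        g = GenotypeMatrix(calls, list(clean_geno.line_ids),
                           clean_geno.marker_map.copy())
        out = bm.filter_lines(g)
        assert out.n_lines == 94

    def test_filters_idempotent(self, clean_geno):
        noisy = apply_gbs_noise(clean_geno, 0.1, 0.04, seed=2)
        once = bm.filter_snps(noisy)
        twice = bm.filter_snps(once)
        assert np.array_equal(once.calls, twice.calls)
        l_once = bm.filter_lines(once)
        l_twice = bm.filter_lines(l_once)
        assert l_once.line_ids == l_twice.line_ids
        u_once = bm.remove_unlinked_snps(l_once)
        u_twice = bm.remove_unlinked_snps(u_once)
        assert np.array_equal(u_once.calls, u_twice.calls)


class TestSimilarity:
    def test_identical_columns(self):
        col = np.array([A, B, A, B] * 5, dtype=np.int8)
        assert bm.pairwise_similarity(col, col) == pytest.approx(1.0)

    def test_anticorrelated_columns(self):
        col = np.array([A, B, A, B] * 5, dtype=np.int8)
        assert bm.pairwise_similarity(col, -col) == pytest.approx(1.0)

    def test_partial_agreement(self):
        a = np.array([A] * 95, dtype=np.int8)
        b = a.copy()
        b[:5] = B  # 90 of 95 agree
        assert bm.pairwise_similarity(a, b) == pytest.approx(90 / 95)

    def test_too_few_comparable_is_nan(self):
        a = np.array([A] * 5 + [M] * 20, dtype=np.int8)
        b = np.array([A] * 25, dtype=np.int8)
        assert np.isnan(bm.pairwise_similarity(a, b))

    def test_het_and_missing_excluded(self):
        a = np.array([A, B] * 10, dtype=np.int8)
        b = a.copy()
        b[:4] = H  # excluded pairs do not change similarity
        assert bm.pairwise_similarity(a, b) == pytest.approx(1.0)


class TestUnlinkedRemoval:
    def test_identical_snps_all_retained(self):
        rng = np.random.default_rng(3)
        col = rng.choice(np.array([A, B], dtype=np.int8), size=97)
        g = _geno(np.tile(col[:, None], (1, 8)))
        out = bm.remove_unlinked_snps(g)
        assert out.n_snps == 8

    def test_shuffled_snp_removed(self):
        """An independently shuffled column among identical ones is dropped."""
        rng = np.random.default_rng(4)
        col = rng.choice(np.array([A, B], dtype=np.int8), size=97)
        removed = 0
        for rep in range(100):
            calls = np.tile(col[:, None], (1, 9))
            calls[:, 4] = rng.permutation(col)
            g = _geno(calls)
            out = bm.remove_unlinked_snps(g)
            removed += "m4" not in out.marker_ids
        assert removed == 100

    def test_noise_free_simulation_keeps_everything(self, clean_geno):
        out = bm.remove_unlinked_snps(clean_geno)
        assert out.n_snps == clean_geno.n_snps

    def test_single_snp_chromosome_warns_and_keeps(self):
        calls = np.array([[A], [B], [A], [B]] * 5, dtype=np.int8)
        g = _geno(calls)
        with pytest.warns(UserWarning):
            out = bm.remove_unlinked_snps(g)
        assert out.n_snps == 1


def _pattern_hash_bins(geno):
    """Brute-force oracle: group consecutive SNPs with identical call
    vectors (per chromosome)."""
    n_bins = []
    for chrom, sl in geno.chrom_slices().items():
        prev = None
        count = 0
        for j in range(sl.start, sl.stop):
            key = geno.calls[:, j].tobytes()
            if key != prev:
                count += 1
                prev = key
        n_bins.append(count)
    return n_bins


class TestMergeBins:
    def test_identical_chromosome_single_bin(self):
        rng = np.random.default_rng(5)
        col = rng.choice(np.array([A, B], dtype=np.int8), size=97)
        g = _geno(np.tile(col[:, None], (1, 100)))
        out = bm.merge_bins(g)
        assert out.n_bins == 1
        assert out.bins.loc[0, "n_snps"] == 100
        assert np.array_equal(out.bin_calls[:, 0], col)

    def test_matches_pattern_hash_oracle_noise_free(self, clean_geno):
        out = bm.merge_bins(clean_geno, threshold=1.0)
        expected = _pattern_hash_bins(clean_geno)
        got = out.bins.groupby("chrom", sort=False).size().tolist()
        assert got == expected

    def test_alternating_patterns_never_merge(self):
        rng = np.random.default_rng(6)
        pat1 = rng.choice(np.array([A, B], dtype=np.int8), size=97)
        # orientation-free similarity to pat1 must be < 0.95 either way
        pat2 = pat1.copy()
        flip = rng.permutation(97)[:48]
        pat2[flip] = -pat2[flip]
        calls = np.column_stack([pat1 if j % 2 == 0 else pat2
                                 for j in range(10)])
        out = bm.merge_bins(_geno(calls))
        assert out.n_bins == 10

    def test_lower_threshold_never_more_bins(self, clean_geno):
        noisy = apply_gbs_noise(clean_geno, 0.05, 0.02, seed=7)
        n_tight = bm.merge_bins(noisy, threshold=0.999).n_bins
        n_mid = bm.merge_bins(noisy, threshold=0.95).n_bins
        n_loose = bm.merge_bins(noisy, threshold=0.85).n_bins
        assert n_loose <= n_mid <= n_tight

    def test_partition_property(self, clean_geno):
        out = bm.merge_bins(clean_geno)
        members = [j for bin_members in out.members for j in bin_members]
        assert members == list(range(clean_geno.n_snps))
        assert out.bins["n_snps"].sum() == clean_geno.n_snps

    def test_consensus_majority_tie_is_missing(self):
        # two SNPs disagreeing on one line -> that line's consensus missing
        col1 = np.array([A] * 20, dtype=np.int8)
        col2 = col1.copy()
        col2[0] = B
        out = bm.merge_bins(_geno(np.column_stack([col1, col2])))
        assert out.n_bins == 1
        assert out.bin_calls[0, 0] == M
        assert np.all(out.bin_calls[1:, 0] == A)


class TestMapDistances:
    def test_haldane_closed_form(self):
        assert bm.haldane_cM(0.0) == pytest.approx(0.0)
        assert bm.haldane_cM(0.25) == pytest.approx(-50 * np.log(0.5))
        assert np.isnan(bm.haldane_cM(0.5))

    def test_estimated_length_within_ten_percent(self):
        """2000 lines on a 150 cM chromosome recover the map length."""
        from pgebv.simulate import GeneticMapSpec
        pos = np.linspace(0, 150, 40)
        spec = GeneticMapSpec([("c1", 150.0)], {"c1": pos})
        g = simulate_dh_genotypes(spec, 2000, seed=9)
        binmap = bm.merge_bins(g, threshold=1.0)
        binmap = bm.estimate_map_distances(binmap)
        total = bm.estimated_map_length(binmap)
        assert abs(total - 150.0) < 15.0

    def test_zero_recombination_zero_distance(self):
        col = np.array([A, B] * 20, dtype=np.int8)
        g = _geno(np.column_stack([col, col]), positions=np.array([0.0, 5.0]))
        binmap = bm.merge_bins(g, threshold=1.0)
        assert binmap.n_bins == 1  # identical -> merged, no distance to test

    def test_full_qc_pipeline_on_noisy_default(self, mini_study):
        _, noisy, _, _ = mini_study
        binmap, report = bm.build_binmap(noisy)
        assert report["n_bins"] == binmap.n_bins
        assert binmap.n_bins < noisy.n_snps
        assert (binmap.bins["n_snps"] >= 1).all()
        # bins never span chromosomes and follow map order
        chrom_order = [c for c, _ in binmap.bins.groupby("chrom", sort=False)]
        assert chrom_order == [f"chr{i}" for i in range(1, 11)]
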