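import numpy as np
import pandas as pd
import pytest

from oracles import binomial_tail
from neighborscan.duplication_repeats import (
    compare_hit_distributions,
    feature_enrichment_permutation,
    interval_counts_in_regions,
    paralog_fraction,
    sd_binomial_test,
    similarity_hits_per_window,
)
from neighborscan.genome_io import IntervalTrack
from neighborscan.window_scan import GenomicWindow


class TestIntervalCounts:
    regions = [("chr1", 0, 1000)]

    def test_fully_inside(self):
        t = IntervalTrack("sd", [("chr1", 100, 200)], kind="segmental_duplication")
        assert interval_counts_in_regions(t, self.regions) == (1, 0, 0)

    def test_straddling_is_ambiguous(self):
        t = IntervalTrack("sd", [("chr1", 900, 1100)])
        assert interval_counts_in_regions(t, self.regions) == (0, 0, 1)

    def test_empty_track(self):
        assert interval_counts_in_regions(IntervalTrack("sd", []), self.regions) == (0, 0, 0)

    def test_counts_partition_track(self):
        rng = np.random.default_rng(0)
        ivs = [("chr1", int(s), int(s) + int(l))
               for s, l in zip(rng.integers(0, 5000, 200), rng.integers(1, 300, 200))]
        t = IntervalTrack("sd", ivs)
        k_in, k_out, n_amb = interval_counts_in_regions(t, [("chr1", 1000, 3000)])
        assert k_in + k_out + n_amb == len(t)


class TestSdBinomialTest:
    def test_human_segmental_duplications(self):
        # 1630 of 5425 SDs inside 932.50 of 2889.53 Mbp: below expectation
        r = sd_binomial_test(1630, 3795, 932.50, 2889.53)
        assert r.obs_prop == pytest.approx(0.3004, abs=1e-4)
        assert r.exp_prop == pytest.approx(0.3227, abs=1e-4)
        assert r.p > 0.05  # not significant: observed < expected

    def test_k_in_zero(self):
        assert sd_binomial_test(0, 10, 1.0, 10.0).p == 1.0

    def test_exact_small_tail(self):
        assert sd_binomial_test(3, 0, 5.0, 10.0).p == pytest.approx(0.125)

    def test_random_vs_bigint_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n = int(rng.integers(1, 50))
            k = int(rng.integers(0, n + 1))
            L_in = float(rng.uniform(0.1, 4.9))
            p = sd_binomial_test(k, n - k, L_in, 5.0).p
            assert p == pytest.approx(binomial_tail(k, n, L_in / 5.0), abs=1e-12)

    def test_invalid_lengths(self):
        with pytest.raises(ValueError):
            sd_binomial_test(1, 1, 10.0, 5.0)


def window(gene_ids):
    return GenomicWindow(0, "chr1", 0, 1000, list(gene_ids))


def hits(rows):
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "pct_identity"])


class TestSimilarityHits:
    def test_single_copy_region(self):
        prof = similarity_hits_per_window(window(["a", "b", "c"]), hits([]), 95)
        assert prof.hits_per_gene == 1.0  # each gene hits only itself

    def test_amplified_family(self):
        genes = ["f1", "f2", "f3", "f4"]
        rows = [(x, y, 99.0) for i, x in enumerate(genes) for y in genes[i + 1:]]
        prof = similarity_hits_per_window(window(genes), hits(rows), 95)
        assert prof.hits_per_gene == 4.0  # N-fold family -> N hits per gene

    def test_one_pair_of_four(self):
        prof = similarity_hits_per_window(
            window(["a", "b", "c", "d"]), hits([("a", "b", 96.0)]), 95)
        assert prof.hits_per_gene == pytest.approx(1.5)  # (2+2+1+1)/4

    def test_invariance_to_orientation_and_duplication(self):
        w = window(["a", "b", "c"])
        h1 = hits([("a", "b", 96.0)])
        h2 = hits([("b", "a", 96.0), ("a", "b", 96.0), ("a", "b", 96.0)])
        assert (similarity_hits_per_window(w, h1, 95).hits_per_gene
                == similarity_hits_per_window(w, h2, 95).hits_per_gene)

    def test_threshold_excludes_weak_hits(self):
        prof = similarity_hits_per_window(
            window(["a", "b"]), hits([("a", "b", 96.0)]), 98)
        assert prof.hits_per_gene == 1.0

    def test_empty_window_errors(self):
        with pytest.raises(ValueError):
            similarity_hits_per_window(window([]), hits([]), 95)


class TestCompareHitDistributions:
    def test_identical_multisets(self):
        t, p = compare_hit_distributions([1.0, 1.5, 2.0], [2.0, 1.0, 1.5])
        assert t == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_equal_constants(self):
        assert compare_hit_distributions([1.0, 1.0], [1.0, 1.0]) == (0.0, 1.0)

    def test_well_separated_groups(self):
        rng = np.random.default_rng(11)
        x = rng.normal(1.0, 0.01, size=50)
        y = rng.normal(2.0, 0.01, size=50)
        _, p = compare_hit_distributions(x, y)
        assert p < 1e-10


class TestFeatureEnrichmentPermutation:
    chrom_lengths = {"chr1": 1_000_000}

    def test_maximal_statistic_floor(self):
        # every feature inside regions covering 10% of the genome, spread so
        # that no random placement recovers the maximal statistic: p hits its
        # 1/(n_perm+1) floor
        points = list(range(96_000, 144_001, 2_000)) + list(range(701_000, 749_001, 2_000))
        track = IntervalTrack("sine", [("chr1", s, s + 10) for s in points],
                              kind="repeat")
        regions = [("chr1", 95_000, 145_000), ("chr1", 700_000, 750_000)]
        p = feature_enrichment_permutation(track, regions, self.chrom_lengths,
                                           n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        track = IntervalTrack("sine", [("chr1", int(s), int(s) + 10)
                                       for s in rng.integers(0, 999_000, 300)])
        regions = [("chr1", 0, 200_000), ("chr1", 500_000, 600_000)]
        args = (track, regions, self.chrom_lengths)
        p1 = feature_enrichment_permutation(*args, n_perm=199, seed=42)
        p2 = feature_enrichment_permutation(*args, n_perm=199, seed=42)
        assert p1 == p2

    def test_null_pvalue_uniformity(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        regions = [("chr1", 0, 250_000), ("chr1", 400_000, 650_000)]  # 50%
        ps = []
        for seed in range(40):
            track = IntervalTrack(
                "f", [("chr1", int(s), int(s) + 5)
                      for s in rng.integers(0, 999_000, 150)])
            ps.append(feature_enrichment_permutation(
                track, regions, self.chrom_lengths, n_perm=199, seed=seed))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_region_longer_than_chromosome(self):
        track = IntervalTrack("f", [("chr1", 0, 5)])
        with pytest.raises(ValueError):
            feature_enrichment_permutation(
                track, [("chr1", 0, 2_000_000)], self.chrom_lengths, n_perm=99, seed=0)


class TestParalogFraction:
    def test_counting(self):
        assert paralog_fraction(["g1", "g2", "g3", "g4"], [("g1", "g9")]) == 0.25

    def test_no_pairs(self):
        assert paralog_fraction(["g1", "g2"], []) == 0.0

    def test_all_paired(self):
        assert paralog_fraction(["g1", "g2"], [("g1", "g2")]) == 1.0

    def test_empty_region_errors(self):
        with pytest.raises(ValueError):
            paralog_fraction([], [("a", "b")])
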