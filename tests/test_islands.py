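"""Threshold, window enumeration, resampling null, island calls, enrichment."""

import math

import numpy as np
import pytest
from scipy import stats

from poolscape.io_formats import GeneInterval
from poolscape.islands import (
    Island,
    call_islands,
    enrich_terms,
    enumerate_windows,
    fst_threshold,
    genes_in_islands,
    resample_null,
    score_windows,
    shared_islands,
    window_pvalue,
)
from poolscape.poolfreq import BiallelicSite


def make_sites(fsts, chrom="chr1", start_pos=100, spacing=10):
    return [
        BiallelicSite(
            chrom=chrom,
            pos=start_pos + i * spacing,
            major="A",
            minor="T",
            coverage=(100, 100),
            minor_counts=(10, 10),
            freqs=(0.1, 0.1),
            maf=0.1,
            fst=f,
        )
        for i, f in enumerate(fsts)
    ]


class TestFstThreshold:
    def test_interpolated_quantile_1_to_1000(self):
        values = list(range(1, 1001))
        thr = fst_threshold(values, 0.99)
        assert thr == pytest.approx(990.01)
        assert sum(v > thr for v in values) == 10

    def test_interpolated_quantile_1_to_100(self):
        values = list(range(1, 101))
        thr = fst_threshold(values, 0.99)
        assert thr == pytest.approx(99.01)
        assert sum(v > thr for v in values) == 1

    def test_degenerate_all_equal(self):
        values = [0.25] * 200
        thr = fst_threshold(values)
        assert thr == 0.25
        assert sum(v > thr for v in values) == 0

    def test_too_few_values_error(self):
        with pytest.raises(ValueError, match="100"):
            fst_threshold([0.1] * 99)


class TestEnumerateWindows:
    @pytest.mark.parametrize("n,expected", [(14, 3), (9, 0), (10, 1), (11, 1), (12, 2)])
    def test_window_counts(self, n, expected):
        wins = enumerate_windows(make_sites([0.1] * n))
        assert len(wins) == expected
        assert [w.start_ordinal for w in wins] == list(range(0, 2 * expected, 2))

    def test_windows_never_cross_chromosomes(self):
        sites = make_sites([0.1] * 9, chrom="chr1") + make_sites(
            [0.1] * 9, chrom="chr2"
        )
        assert enumerate_windows(sites) == []

    def test_unsorted_positions_raise(self):
        sites = make_sites([0.1] * 12)
        sites[3], sites[4] = sites[4], sites[3]
        with pytest.raises(ValueError, match="sorted"):
            enumerate_windows(sites)

    def test_interleaved_chromosome_blocks_raise(self):
        sites = (
            make_sites([0.1] * 3, chrom="chr1")
            + make_sites([0.1] * 3, chrom="chr2")
            + make_sites([0.1] * 3, chrom="chr1", start_pos=900)
        )
        with pytest.raises(ValueError, match="sorted"):
            enumerate_windows(sites)


class TestResampleNull:
    def _vector_with_exact_outlier_fraction(self, n=10_000, frac=0.01):
        # 99% low values, 1% high values; the interpolated 0.99-quantile
        # falls between them, so the strict-outlier fraction is exactly frac
        values = np.concatenate(
            [np.full(int(n * (1 - frac)), 0.1), np.full(int(n * frac), 0.9)]
        )
        return values

    def test_matches_analytic_binomial_tail(self):
        values = self._vector_with_exact_outlier_fraction()
        thr = fst_threshold(values, 0.99)
        null = resample_null(values, thr, resamples=100_000, seed=7)
        assert null.p_hat == pytest.approx(0.01)
        analytic = 1.0 - stats.binom.cdf(2, 10, 0.01)
        mc_se = math.sqrt(analytic * (1 - analytic) / null.resamples)
        assert abs(null.tail_probability(3) - analytic) <= 3 * mc_se

    def test_threshold_above_max_gives_all_mass_at_zero(self):
        values = np.linspace(0, 1, 500)
        null = resample_null(values, 2.0, resamples=1000, seed=1)
        assert null.histogram[0] == 1000
        assert null.tail_probability(1) == 0.0

    def test_same_seed_reproduces_histogram(self):
        values = np.linspace(0, 1, 500)
        thr = fst_threshold(values)
        a = resample_null(values, thr, resamples=5000, seed=42)
        b = resample_null(values, thr, resamples=5000, seed=42)
        assert np.array_equal(a.histogram, b.histogram)

    def test_histogram_sums_to_resample_count(self):
        values = np.linspace(0, 1, 500)
        null = resample_null(values, 0.5, resamples=5000, seed=3)
        assert null.histogram.sum() == 5000

    def test_pvalue_monotone_in_outlier_count(self):
        values = self._vector_with_exact_outlier_fraction()
        thr = fst_threshold(values)
        null = resample_null(values, thr, resamples=50_000, seed=5)
        tails = [null.tail_probability(c) for c in range(11)]
        assert tails[0] == 1.0
        assert all(a >= b for a, b in zip(tails, tails[1:]))


class TestWindowPvalue:
    def test_zero_outliers_is_pvalue_one(self):
        (win,) = enumerate_windows(make_sites([0.1] * 10))
        values = np.linspace(0, 1, 500)
        null = resample_null(values, 0.99, resamples=1000, seed=1)
        score_windows([win], threshold=0.99, null=null)
        assert win.outlier_count == 0
        assert window_pvalue(win, null) == 1.0

    def test_strict_inequality_at_threshold(self):
        (win,) = enumerate_windows(make_sites([0.5] * 10))
        score_windows([win], threshold=0.5)
        assert win.outlier_count == 0


class TestCallIslands:
    def _scored_windows(self, sig_flags, chrom="chr1"):
        """Build step-2 windows over len(sig_flags) ordinals with set p."""
        n = 2 * len(sig_flags) + 8
        wins = enumerate_windows(make_sites([0.1] * n, chrom=chrom))
        for w, sig in zip(wins, sig_flags):
            w.outlier_count = 5 if sig else 0
            w.p_value = 1e-5 if sig else 1.0
        for w in wins[len(sig_flags):]:
            w.outlier_count, w.p_value = 0, 1.0
        return wins

    def test_overlapping_windows_merge(self):
        wins = self._scored_windows([True, True])
        (island,) = call_islands(wins)
        assert island.n_snps == 12
        assert island.window_indices == (0, 1)
        assert island.start == wins[0].start_pos
        assert island.end == wins[1].end_pos

    def test_no_significant_windows_no_islands(self):
        assert call_islands(self._scored_windows([False, False])) == []

    def test_islands_are_per_chromosome(self):
        wins = self._scored_windows([True], chrom="chr6") + self._scored_windows(
            [True], chrom="chr12"
        )
        islands = call_islands(wins)
        assert sorted(i.chrom for i in islands) == ["chr12", "chr6"]

    def test_disjoint_significant_windows_stay_separate(self):
        # windows 0 and 6 (ordinals 0-9 and 12-21) share no SNP
        wins = self._scored_windows([True, False, False, False, False, False, True])
        islands = call_islands(wins)
        assert len(islands) == 2

    def test_alpha_is_strict(self):
        wins = self._scored_windows([True])
        wins[0].p_value = 0.001
        assert call_islands(wins, alpha=0.001) == []


class TestSharedIslands:
    def _island(self, chrom, start, end):
        return Island(chrom, start, end, (0,), 10, 1e-5)

    def test_overlap_is_intersected(self):
        shared = shared_islands(
            [self._island("chr6", 100, 200)], [self._island("chr6", 150, 300)]
        )
        assert shared == [("chr6", 150, 200)]

    def test_different_chromosomes_do_not_share(self):
        assert (
            shared_islands(
                [self._island("chr6", 100, 200)],
                [self._island("chr12", 100, 200)],
            )
            == []
        )

    def test_abutting_spans_do_not_share(self):
        assert (
            shared_islands(
                [self._island("chr6", 100, 200)],
                [self._island("chr6", 201, 300)],
            )
            == []
        )


class TestGenesInIslands:
    ISLAND = Island("chr1", 450, 600, (0,), 10, 1e-5)

    @pytest.mark.parametrize(
        "start,end,included",
        [(100, 500, True), (100, 400, False), (100, 1000, True), (600, 700, True)],
    )
    def test_one_bp_overlap_rule(self, start, end, included):
        genes = [GeneInterval("chr1", start, end, "gA")]
        hits = genes_in_islands([self.ISLAND], genes)
        assert ("gA" in hits) == included

    def test_output_deduplicated_and_sorted(self):
        genes = [
            GeneInterval("chr1", 440, 460, "gB"),
            GeneInterval("chr1", 500, 700, "gA"),
            GeneInterval("chr1", 430, 470, "gB"),
        ]
        assert genes_in_islands([self.ISLAND], genes) == ["gA", "gB"]


class TestEnrichTerms:
    def test_exact_hypergeometric_tail(self):
        # N = 100, K = 10, n = 10, k = 5: exact enumeration oracle
        background = [f"g{i}" for i in range(100)]
        term = {"t": background[:10]}
        candidates = background[:5] + background[50:55]
        (res,) = enrich_terms(candidates, background, term)
        expected = sum(
            math.comb(10, i) * math.comb(90, 10 - i) for i in range(5, 11)
        ) / math.comb(100, 10)
        assert res.overlap == 5
        assert res.p_value == pytest.approx(expected, rel=1e-12)

    def test_zero_overlap_is_pvalue_one(self):
        background = [f"g{i}" for i in range(50)]
        (res,) = enrich_terms(
            background[:5], background, {"t": background[40:45]}
        )
        assert res.overlap == 0
        assert res.p_value == pytest.approx(1.0)

    def test_candidates_equal_background_forces_full_overlap(self):
        background = [f"g{i}" for i in range(30)]
        results = enrich_terms(
            background, background, {"a": background[:7], "b": background[7:9]}
        )
        for r in results:
            assert r.overlap == r.term_size
            assert r.p_value == pytest.approx(1.0)

    def test_bonferroni_counts_only_nonempty_terms(self):
        background = [f"g{i}" for i in range(100)]
        terms = {
            "real1": background[:10],
            "real2": background[10:20],
            "empty": ["not_in_background"],
        }
        results = enrich_terms(background[:10], background, terms)
        assert len(results) == 2
        for r in results:
            assert r.p_bonferroni == pytest.approx(min(1.0, r.p_value * 2))
            assert r.p_bonferroni >= r.p_value

    def test_candidate_outside_background_errors(self):
        with pytest.raises(ValueError, match="absent"):
            enrich_terms(["x"], ["a", "b"], {"t": ["a"]})
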