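"""Window ranking: filtering, binning, merging, scoring, locus lookup."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lociscape.windows as lw
from lociscape.windows import (
    BinStats,
    GenomeBinning,
    compute_bin_stats,
    filter_transcripts,
    locate_locus,
    merge_windows,
    score_and_rank,
)

from conftest import make_transcript, random_transcripts
from oracles import merge_oracle, rank_oracle


def occupancy_to_stats(pattern, chrom="chr1"):
    return [
        BinStats(chrom=chrom, bin_index=i, hits=int(v), total_length=100 * int(v),
                 weighted_coverage=10.0 * int(v))
        for i, v in enumerate(pattern)
    ]


class TestFilterTranscripts:
    def test_thresholds_inclusive(self):
        at_threshold = make_transcript(length=300, fpkm=0.3)
        assert filter_transcripts([at_threshold]) == [at_threshold]

    @pytest.mark.parametrize(
        "length,fpkm,kept",
        [(299, 0.3, False), (300, 0.29, False), (301, 5.0, True), (50, 50.0, False)],
    )
    def test_threshold_boundaries(self, length, fpkm, kept):
        t = make_transcript(length=length, fpkm=fpkm)
        assert bool(filter_transcripts([t])) is kept

    def test_empty_input(self):
        assert filter_transcripts([]) == []

    def test_mature_not_span_length_is_filtered(self):
        # 200 nt mature over a 1 kb genomic span: fails the >=300 nt filter
        t = make_transcript(exons=((0, 100), (900, 1000)), fpkm=1.0)
        assert t.end - t.start == 1000 and t.mature_length == 200
        assert filter_transcripts([t]) == []

    def test_annotation_overlap_drops_on_either_strand(self):
        plus = make_transcript(tid="p", start=1000, length=400, strand="+")
        minus = make_transcript(tid="m", start=5000, length=400, strand="-")
        ann = [("chr1", 1300, 1350)]
        kept = filter_transcripts([plus, minus], known_annotation=ann)
        assert [t.id for t in kept] == ["m"]

    def test_matches_bruteforce_on_random_records(self, rng):
        records = random_transcripts(rng, 200, {"chr1": 10_000_000})
        kept = filter_transcripts(records, min_length=300, min_fpkm=0.3)
        expected = [
            r for r in records if r.mature_length >= 300 and r.expression >= 0.3
        ]
        assert kept == expected

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_transcripts([], min_length=-1)


class TestComputeBinStats:
    BINNING = GenomeBinning({"chr1": 1_000_000}, bin_size=100_000)

    def test_five_prime_bin_assignment(self):
        t = make_transcript(start=150_000, length=1000)
        stats = compute_bin_stats([t], self.BINNING)
        assert [b.hits for b in stats] == [0, 1] + [0] * 8

    def test_minus_strand_uses_three_prime_end_coordinate(self):
        # minus-strand 5' end is end-1: a transcript spanning a bin edge
        # is assigned to the bin of its rightmost base
        t = make_transcript(start=99_500, length=1000, strand="-")
        stats = compute_bin_stats([t], self.BINNING)
        assert stats[1].hits == 1 and stats[0].hits == 0

    def test_weighted_coverage_is_length_times_fpkm(self):
        t = make_transcript(length=1000, fpkm=2.0)
        stats = compute_bin_stats([t], self.BINNING)
        assert stats[0].weighted_coverage == pytest.approx(2000.0)
        assert stats[0].total_length == 1000

    def test_unknown_chromosome_names_offender(self):
        t = make_transcript(tid="stray", chrom="chrUn")
        with pytest.raises(ValueError, match="stray"):
            compute_bin_stats([t], self.BINNING)

    def test_matches_bruteforce_accumulation(self, rng):
        sizes = {"chr1": 2_000_000, "chr2": 1_500_000}
        binning = GenomeBinning(sizes, bin_size=100_000)
        records = random_transcripts(rng, 300, sizes)
        stats = compute_bin_stats(records, binning)
        acc = {}
        for r in records:
            key = (r.chrom, r.five_prime // 100_000)
            h, l, w = acc.get(key, (0, 0, 0.0))
            acc[key] = (h + 1, l + r.mature_length, w + r.mature_length * r.expression)
        for b in stats:
            h, l, w = acc.get((b.chrom, b.bin_index), (0, 0, 0.0))
            assert (b.hits, b.total_length) == (h, l)
            assert b.weighted_coverage == pytest.approx(w)

    def test_all_overlapping_mode_apportions_by_overlap(self):
        binning = GenomeBinning({"chr1": 300_000}, bin_size=100_000)
        t = make_transcript(start=50_000, length=100_000, fpkm=1.0)
        stats = compute_bin_stats([t], binning, assignment="all_overlapping")
        assert [b.hits for b in stats] == [1, 1, 0]
        assert stats[0].total_length == stats[1].total_length == 50_000

    def test_empty_bins_reported_with_zeros(self):
        stats = compute_bin_stats([], self.BINNING)
        assert len(stats) == 10
        assert all(b.hits == 0 and b.total_length == 0 for b in stats)


class TestMergeWindows:
    def test_two_bin_gap_does_not_split(self):
        wins = merge_windows(occupancy_to_stats([1, 0, 0, 1]))
        assert len(wins) == 1
        assert wins[0].member_bins == [0, 1, 2, 3]

    def test_three_bin_gap_splits(self):
        wins = merge_windows(occupancy_to_stats([1, 0, 0, 0, 1]))
        assert len(wins) == 2
        assert [w.member_bins for w in wins] == [[0], [4]]

    def test_interior_empty_bins_contribute_zero_criteria(self):
        wins = merge_windows(occupancy_to_stats([1, 0, 0, 1]))
        assert wins[0].hits == 2 and wins[0].total_length == 200

    def test_windows_never_cross_chromosomes(self):
        stats = occupancy_to_stats([1], chrom="chr1") + occupancy_to_stats(
            [1], chrom="chr2"
        )
        wins = merge_windows(stats)
        assert len(wins) == 2
        assert {w.chrom for w in wins} == {"chr1", "chr2"}

    def test_bin_aligned_genomic_coordinates(self):
        binning = GenomeBinning({"chr1": 450_000}, bin_size=100_000)
        stats = occupancy_to_stats([0, 1, 0, 1, 1])
        wins = merge_windows(stats, binning=binning)
        assert (wins[0].start, wins[0].end) == (100_000, 450_000)  # clipped end

    @given(
        pattern=st.lists(st.integers(0, 1), min_size=1, max_size=12),
        max_gap=st.integers(0, 3),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_runlength_oracle(self, pattern, max_gap):
        wins = merge_windows(occupancy_to_stats(pattern), max_gap_bins=max_gap)
        got = [(w.member_bins[0], w.member_bins[-1]) for w in wins]
        assert got == merge_oracle(pattern, max_gap)

    def test_idempotent_on_window_members(self):
        pattern = [1, 0, 1, 1, 0, 0, 0, 1, 0, 0, 1]
        stats = occupancy_to_stats(pattern)
        for w in merge_windows(stats):
            member_stats = [stats[i] for i in w.member_bins]
            sub = merge_windows(member_stats, max_gap_bins=2)
            assert len(sub) == 1
            assert sub[0].member_bins == w.member_bins
            assert (sub[0].hits, sub[0].total_length) == (w.hits, w.total_length)


class TestScoreAndRank:
    def test_single_window(self):
        wins = merge_windows(occupancy_to_stats([1]))
        ranked = score_and_rank(wins)
        w = ranked[0]
        assert w.criterion_ranks == (1, 1, 1)
        assert w.overall_score == 3 and w.overall_rank == 1
        assert w.n_windows_total == 1

    def test_dominant_window_ranks_first(self, rng):
        wins = []
        for k in range(10):
            wins.append(
                lw.WindowScore(
                    chrom="chr1", start=k * 10, end=k * 10 + 1, member_bins=[k],
                    hits=int(rng.integers(1, 50)),
                    total_length=int(rng.integers(100, 5000)),
                    weighted_coverage=float(rng.uniform(1, 100)),
                )
            )
        wins.append(
            lw.WindowScore(chrom="chr2", start=0, end=1, member_bins=[0],
                           hits=100, total_length=10_000, weighted_coverage=1e6)
        )
        ranked = score_and_rank(wins)
        assert ranked[-1].overall_rank == 1

    def test_matches_sort_oracle_on_random_windows(self, rng):
        for _ in range(20):
            wins = [
                lw.WindowScore(
                    chrom=f"chr{rng.integers(1, 4)}", start=int(rng.integers(0, 100)) * 7,
                    end=1_000_000, member_bins=[0],
                    hits=int(rng.integers(0, 5)),
                    total_length=int(rng.integers(0, 4) * 100),
                    weighted_coverage=float(rng.integers(0, 4) * 10),
                )
                for _ in range(20)
            ]
            ranked = score_and_rank(wins)
            rows = [
                (w.chrom, w.start, w.hits, w.total_length, w.weighted_coverage)
                for w in wins
            ]
            for w, (cr, score, overall) in zip(wins, rank_oracle(rows)):
                assert w.criterion_ranks == cr
                assert w.overall_score == score
                assert w.overall_rank == overall

    def test_overall_rank_is_permutation(self, rng):
        wins = [
            lw.WindowScore(chrom="chr1", start=i, end=i + 1, member_bins=[i],
                           hits=int(rng.integers(0, 3)), total_length=100,
                           weighted_coverage=float(rng.integers(0, 3)))
            for i in range(30)
        ]
        ranked = score_and_rank(wins)
        assert sorted(w.overall_rank for w in ranked) == list(range(1, 31))

    def test_raw_sum_mode_orders_by_raw_criteria(self):
        small = lw.WindowScore(chrom="chr1", start=0, end=1, member_bins=[0],
                               hits=1, total_length=100, weighted_coverage=10.0)
        big = lw.WindowScore(chrom="chr1", start=5, end=6, member_bins=[5],
                             hits=2, total_length=20_000, weighted_coverage=500.0)
        ranked = score_and_rank([small, big], score_mode="raw_sum")
        assert big.overall_rank == 1 and small.overall_rank == 2

    def test_empty_window_list_rejected(self):
        with pytest.raises(ValueError):
            score_and_rank([])

    def test_adding_transcript_weakly_improves_ranks(self, rng):
        # monotonicity: adding one transcript to a window cannot worsen
        # any of its criterion ranks
        base = [
            lw.WindowScore(chrom="chr1", start=i * 10, end=i * 10 + 1, member_bins=[i],
                           hits=int(rng.integers(1, 10)),
                           total_length=int(rng.integers(100, 2000)),
                           weighted_coverage=float(rng.uniform(10, 100)))
            for i in range(15)
        ]
        import copy

        before = copy.deepcopy(base)
        score_and_rank(before)
        after = copy.deepcopy(base)
        target = after[7]
        target.hits += 1
        target.total_length += 500
        target.weighted_coverage += 500 * 1.0
        score_and_rank(after)
        for b, a in zip(before[7].criterion_ranks, after[7].criterion_ranks):
            assert a <= b


class TestLocateLocus:
    def _ranked(self, pattern, binning=None):
        binning = binning or GenomeBinning({"chr1": 2_000_000}, bin_size=100_000)
        return score_and_rank(merge_windows(occupancy_to_stats(pattern), binning=binning))

    def test_contained_locus_single_window(self):
        wins = self._ranked([1, 1, 1, 0, 0, 0, 0, 1])
        rep = locate_locus(wins, ("chr1", 50_000, 250_000))
        assert rep.single_window is True
        assert len(rep.windows) == 1

    def test_locus_spanning_two_windows(self):
        wins = self._ranked([1, 0, 0, 0, 1])
        rep = locate_locus(wins, ("chr1", 50_000, 450_000))
        assert rep.single_window is False
        assert len(rep.windows) == 2

    def test_no_overlap_empty_report(self):
        wins = self._ranked([1, 0, 0, 0, 0, 0, 0, 0])
        rep = locate_locus(wins, ("chr1", 500_000, 600_000))
        assert rep.windows == [] and rep.single_window is False
        assert rep.best_rank is None

    def test_matches_bruteforce_intersection(self, rng):
        wins = self._ranked([int(v) for v in rng.integers(0, 2, 20)],
                            binning=GenomeBinning({"chr1": 2_000_000}, bin_size=100_000))
        for _ in range(50):
            s = int(rng.integers(0, 1_900_000))
            e = s + int(rng.integers(1, 500_000))
            rep = locate_locus(wins, ("chr1", s, e))
            expected = {
                (w.start, w.end) for w in wins if w.start < e and s < w.end
            }
            assert {(w.start, w.end) for w in rep.windows} == expected


class TestConservation:
    def test_criteria_conserved_through_windowing(self, rng):
        sizes = {"chr1": 5_000_000, "chr2": 3_000_000}
        binning = GenomeBinning(sizes, bin_size=100_000)
        records = random_transcripts(rng, 150, sizes)
        stats = compute_bin_stats(records, binning)
        wins = merge_windows(stats, binning=binning)
        assert sum(w.hits for w in wins) == len(records)
        assert sum(w.total_length for w in wins) == sum(
            r.mature_length for r in records
        )
        assert sum(w.weighted_coverage for w in wins) == pytest.approx(
            sum(r.mature_length * r.expression for r in records)
        )
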