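"""Genome-wide lncRNA-enrichment window ranking.

The procedure: filter assembled transcripts by mature length and
expression, tile the genome into fixed-size bins (default 100 kb),
accumulate three per-bin criteria (transcript hits, summed mature
length, weighted coverage = length x FPKM), merge expressing bins into
windows terminated by runs of more than ``max_gap_bins`` empty bins,
then rank windows genome-wide on each criterion and combine the ranks
into an overall score (lower = more enriched).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import TranscriptRecord


@dataclass(frozen=True)
class GenomeBinning:
    """Fixed-width tiling of each chromosome into half-open bins."""

    chrom_sizes: dict[str, int]
    bin_size: int = 100_000

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom}: size must be positive")

    def n_bins(self, chrom: str) -> int:
        size = self.chrom_sizes[chrom]
        return -(-size // self.bin_size)

    def bin_index(self, chrom: str, pos: int) -> int:
        if pos < 0 or pos >= self.chrom_sizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return pos // self.bin_size

    def bin_span(self, chrom: str, index: int) -> tuple[int, int]:
        start = index * self.bin_size
        return start, min(start + self.bin_size, self.chrom_sizes[chrom])


@dataclass
class BinStats:
    """Per-bin accumulation of the three window criteria."""

    chrom: str
    bin_index: int
    hits: int = 0
    total_length: int = 0
    weighted_coverage: float = 0.0


@dataclass
class WindowScore:
    """A merged run of bins with its criteria, ranks and overall score.

    ``criterion_ranks`` orders windows genome-wide per criterion with
    1 = largest value; ``overall_score`` is the sum of the three ranks
    and ``overall_rank`` the 1-based position in ascending overall_score.
    """

    chrom: str
    start: int
    end: int
    member_bins: list[int]
    hits: int
    total_length: int
    weighted_coverage: float
    criterion_ranks: tuple[int, int, int] | None = None
    overall_score: float | None = None
    overall_rank: int | None = None
    n_windows_total: int | None = None

    def overlaps(self, start: int, end: int, chrom: str) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end

    def contains(self, start: int, end: int, chrom: str) -> bool:
        return self.chrom == chrom and self.start <= start and end <= self.end


def filter_transcripts(
    records: list[TranscriptRecord],
    min_length: int = 300,
    min_fpkm: float = 0.3,
    known_annotation: list[tuple[str, int, int]] | None = None,
) -> list[TranscriptRecord]:
    """Retain transcripts with mature length >= ``min_length`` and
    expression >= ``min_fpkm`` (both thresholds inclusive).

    ``known_annotation`` is an optional list of (chrom, start, end)
    intervals for annotated exons; transcripts whose genomic span
    overlaps any of them (either strand) are dropped, leaving only
    unannotated transcripts. Input order is preserved.
    """
    if min_length < 0 or min_fpkm < 0:
        raise ValueError("thresholds must be non-negative")
    kept = [
        r for r in records
        if r.mature_length >= min_length and r.expression >= min_fpkm
    ]
    if known_annotation:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in known_annotation:
            by_chrom.setdefault(chrom, []).append((s, e))
        for ivs in by_chrom.values():
            ivs.sort()

        def overlaps_annotation(r: TranscriptRecord) -> bool:
            for s, e in by_chrom.get(r.chrom, ()):
                if s >= r.end:
                    break
                if r.start < e and s < r.end:
                    return True
            return False

        kept = [r for r in kept if not overlaps_annotation(r)]
    return kept


def compute_bin_stats(
    records: list[TranscriptRecord],
    binning: GenomeBinning,
    assignment: str = "five_prime",
) -> list[BinStats]:
    """Accumulate per-bin criteria over whole chromosomes.

    With ``assignment='five_prime'`` (default) each transcript counts in
    exactly one bin — the bin holding its 5'-most coordinate — so the
    three criteria are conserved when summed over bins. With
    ``'all_overlapping'`` a transcript contributes to every bin its span
    touches, with length and coverage apportioned by overlap fraction
    and a hit counted in each.
    Bins with no transcripts are reported with zeros.
    """
    if assignment not in ("five_prime", "all_overlapping"):
        raise ValueError(f"unknown assignment mode: {assignment}")
    stats: dict[tuple[str, int], BinStats] = {}
    for chrom in binning.chrom_sizes:
        for i in range(binning.n_bins(chrom)):
            stats[(chrom, i)] = BinStats(chrom=chrom, bin_index=i)
    for r in records:
        if r.chrom not in binning.chrom_sizes:
            raise ValueError(f"transcript {r.id} on unknown chromosome {r.chrom}")
        if assignment == "five_prime":
            b = stats[(r.chrom, binning.bin_index(r.chrom, r.five_prime))]
            b.hits += 1
            b.total_length += r.mature_length
            b.weighted_coverage += r.mature_length * r.expression
        else:
            first = binning.bin_index(r.chrom, r.start)
            last = binning.bin_index(r.chrom, min(r.end - 1, binning.chrom_sizes[r.chrom] - 1))
            span = r.end - r.start
            for i in range(first, last + 1):
                bs, be = binning.bin_span(r.chrom, i)
                frac = (min(be, r.end) - max(bs, r.start)) / span
                b = stats[(r.chrom, i)]
                b.hits += 1
                b.total_length += int(round(r.mature_length * frac))
                b.weighted_coverage += r.mature_length * r.expression * frac
    return [stats[k] for k in sorted(stats, key=lambda k: (k[0], k[1]))]


def merge_windows(
    bin_stats: list[BinStats],
    max_gap_bins: int = 2,
    binning: GenomeBinning | None = None,
    bin_size: int | None = None,
) -> list[WindowScore]:
    """Merge expressing bins (hits > 0) into windows per chromosome.

    Expressing bins separated by at most ``max_gap_bins`` empty bins
    belong to one window; a longer empty run terminates it. Window span
    runs from the first to the last expressing bin inclusive; interior
    empty bins are counted in the span and member list but contribute
    zero to the criteria. Windows never cross chromosomes. Returned
    windows have criteria filled and ranks unset.

    ``binning`` (or ``bin_size``) converts bin indices to genomic
    coordinates and clips the last bin's end to the chromosome length;
    with neither, coordinates are reported in bin units (size 1), which
    only affects the ``start``/``end`` fields, not the merging.
    """
    if binning is not None:
        bsize = binning.bin_size
    else:
        bsize = bin_size if bin_size is not None else 1
    by_chrom: dict[str, list[BinStats]] = {}
    for b in bin_stats:
        by_chrom.setdefault(b.chrom, []).append(b)
    windows: list[WindowScore] = []
    for chrom in by_chrom:
        bins = sorted(by_chrom[chrom], key=lambda b: b.bin_index)
        run: list[BinStats] = []  # current window's bins, trailing gap trimmed
        gap = 0
        for b in bins:
            if b.hits > 0:
                if run and gap > 0:
                    # re-admit the interior empty bins
                    start_idx = run[-1].bin_index + 1
                    for j in range(start_idx, b.bin_index):
                        run.append(BinStats(chrom=chrom, bin_index=j))
                run.append(b)
                gap = 0
            else:
                gap += 1
                if gap > max_gap_bins and run:
                    windows.append(_finish_window(run, chrom, bsize, binning))
                    run = []
        if run:
            windows.append(_finish_window(run, chrom, bsize, binning))
    windows.sort(key=lambda w: (w.chrom, w.start))
    return windows


def _finish_window(
    run: list[BinStats], chrom: str, bin_size: int, binning: GenomeBinning | None
) -> WindowScore:
    first, last = run[0].bin_index, run[-1].bin_index
    end = (last + 1) * bin_size
    if binning is not None:
        end = min(end, binning.chrom_sizes[chrom])
    return WindowScore(
        chrom=chrom,
        start=first * bin_size,
        end=end,
        member_bins=[b.bin_index for b in run],
        hits=sum(b.hits for b in run),
        total_length=sum(b.total_length for b in run),
        weighted_coverage=sum(b.weighted_coverage for b in run),
    )


def score_and_rank(
    windows: list[WindowScore], score_mode: str = "rank_sum"
) -> list[WindowScore]:
    """Assign per-criterion genome-wide ranks and the overall rank.

    Each criterion (hits, total_length, weighted_coverage) is ranked
    with 1 = largest value; tied values share the minimum rank of their
    group (competition ranking). ``overall_score`` is the sum of the
    three criterion ranks (``rank_sum`` mode, default) or the negated
    sum of the raw criterion values (``raw_sum`` mode, negated so that
    ascending overall_score still means more enriched). ``overall_rank``
    orders windows by ascending overall_score, breaking ties by larger
    weighted_coverage, then by (chrom, start).
    """
    if not windows:
        raise ValueError("cannot rank an empty window list")
    if score_mode not in ("rank_sum", "raw_sum"):
        raise ValueError(f"unknown score_mode: {score_mode}")
    from scipy.stats import rankdata

    n = len(windows)
    crit = {
        "hits": np.array([w.hits for w in windows], dtype=float),
        "total_length": np.array([w.total_length for w in windows], dtype=float),
        "weighted_coverage": np.array([w.weighted_coverage for w in windows], dtype=float),
    }
    # descending competition ranks: 1 = largest
    ranks = {k: rankdata(-v, method="min").astype(int) for k, v in crit.items()}
    for i, w in enumerate(windows):
        w.criterion_ranks = (
            int(ranks["hits"][i]),
            int(ranks["total_length"][i]),
            int(ranks["weighted_coverage"][i]),
        )
        if score_mode == "rank_sum":
            w.overall_score = float(sum(w.criterion_ranks))
        else:
            w.overall_score = -(w.hits + w.total_length + w.weighted_coverage)
        w.n_windows_total = n
    order = sorted(
        range(n),
        key=lambda i: (
            windows[i].overall_score,
            -windows[i].weighted_coverage,
            windows[i].chrom,
            windows[i].start,
        ),
    )
    for rank0, i in enumerate(order):
        windows[i].overall_rank = rank0 + 1
    return windows


@dataclass
class LocusReport:
    """Windows overlapping a locus of interest, best rank first."""

    locus: tuple[str, int, int]
    windows: list[WindowScore] = field(default_factory=list)
    single_window: bool = False

    @property
    def best_rank(self) -> int | None:
        return self.windows[0].overall_rank if self.windows else None


def locate_locus(
    windows: list[WindowScore], locus: tuple[str, int, int]
) -> LocusReport:
    """Report ranked windows overlapping ``locus`` (chrom, start, end)
    and whether the locus is fully contained in a single window."""
    chrom, start, end = locus
    if end <= start:
        raise ValueError("locus end must exceed start")
    hits = [w for w in windows if w.overlaps(start, end, chrom)]
    hits.sort(key=lambda w: (w.overall_rank if w.overall_rank is not None else 0))
    single = any(w.contains(start, end, chrom) for w in hits)
    return LocusReport(locus=locus, windows=hits, single_window=single)
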