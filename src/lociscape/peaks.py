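"""ATAC-seq peak score normalization and reproducibility filtering.

Peak scores (-log10 p from the caller) are converted per sample to a
score per million (SPM): each score divided by the sample's total
score over one million. Sample peak sets are merged greedily, keeping
the most significant peak among overlapping ones; consensus peaks are
then filtered for support in at least ``min_samples`` samples at
SPM >= ``min_spm``. Peak-by-sample fragment counts can additionally be
normalized by each sample's promoter-region insert total.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import PeakRecord

SPM_TOTAL = 1_000_000.0


def to_spm(peaks: list[PeakRecord]) -> list[PeakRecord]:
    """Attach SPM values to one sample's peaks (in place, also returned).

    spm_i = score_i / (sum_j score_j / 1e6), so per-sample SPM values
    sum to one million.
    """
    if not peaks:
        raise ValueError("no peaks supplied")
    sample_ids = {p.sample_id for p in peaks}
    if len(sample_ids) > 1:
        raise ValueError(f"to_spm expects one sample, got {sorted(sample_ids)}")
    total = sum(p.score_raw for p in peaks)
    if total <= 0:
        raise ValueError("total peak score is zero; cannot convert to SPM")
    for p in peaks:
        p.spm = p.score_raw / (total / SPM_TOTAL)
    return peaks


@dataclass
class ConsensusPeak:
    """A kept (non-overlapping) peak with its per-sample support.

    ``support`` maps sample_id -> best SPM among that sample's peaks
    overlapping this interval.
    """

    chrom: str
    start: int
    end: int
    spm: float
    score_raw: float
    source_sample: str
    support: dict[str, float] = field(default_factory=dict)


@dataclass
class MergedPeakSet:
    peaks: list[ConsensusPeak]

    def __len__(self) -> int:
        return len(self.peaks)


def _sort_key(p: PeakRecord) -> tuple:
    # total order: descending spm, descending raw score, then coordinates
    return (-p.spm, -p.score_raw, p.chrom, p.start, p.end, p.sample_id)


def merge_peak_sets(samples: list[list[PeakRecord]]) -> MergedPeakSet:
    """Greedy cross-sample merge keeping the most significant peaks.

    All peaks are pooled and sorted by descending SPM (ties broken by
    descending raw score, then coordinates, making the outcome
    independent of input file order); each peak is kept iff it overlaps
    no already-kept peak. Every kept peak then records, per sample, the
    best-SPM sample peak overlapping it.
    """
    pool = [p for sample in samples for p in sample]
    if any(p.spm is None for p in pool):
        raise ValueError("all peaks must be SPM-converted before merging")
    pool.sort(key=_sort_key)
    kept: list[ConsensusPeak] = []
    kept_by_chrom: dict[str, list[tuple[int, int, int]]] = {}  # (start, end, idx)
    for p in pool:
        ivs = kept_by_chrom.setdefault(p.chrom, [])
        if not _any_overlap(ivs, p.start, p.end):
            kept.append(
                ConsensusPeak(
                    chrom=p.chrom,
                    start=p.start,
                    end=p.end,
                    spm=p.spm,
                    score_raw=p.score_raw,
                    source_sample=p.sample_id,
                )
            )
            insort(ivs, (p.start, p.end, len(kept) - 1))
    for p in pool:
        for s, e, idx in _overlapping(kept_by_chrom.get(p.chrom, []), p.start, p.end):
            cp = kept[idx]
            if p.sample_id not in cp.support or p.spm > cp.support[p.sample_id]:
                cp.support[p.sample_id] = p.spm
    kept.sort(key=lambda c: (c.chrom, c.start, c.end))
    return MergedPeakSet(peaks=kept)


def _any_overlap(ivs: list[tuple[int, int, int]], start: int, end: int) -> bool:
    for _ in _overlapping(ivs, start, end):
        return True
    return False


def _overlapping(ivs: list[tuple[int, int, int]], start: int, end: int):
    """Yield kept intervals overlapping [start, end); ivs sorted by start.

    Kept intervals are pairwise non-overlapping, so at most one kept
    interval starts before ``start`` and still overlaps it.
    """
    i = bisect_left(ivs, (start,))
    if i > 0 and ivs[i - 1][1] > start:
        yield ivs[i - 1]
    while i < len(ivs) and ivs[i][0] < end:
        yield ivs[i]
        i += 1


def reproducibility_filter(
    merged: MergedPeakSet, min_samples: int = 2, min_spm: float = 2.0
) -> MergedPeakSet:
    """Retain consensus peaks supported in at least ``min_samples``
    samples each at SPM >= ``min_spm`` (both thresholds inclusive)."""
    kept = [
        p
        for p in merged.peaks
        if sum(1 for v in p.support.values() if v >= min_spm) >= min_samples
    ]
    return MergedPeakSet(peaks=kept)


def promoter_windows(
    tss: list[tuple[str, int, str]], upstream: int = 300, downstream: int = 100
) -> list[tuple[str, int, int]]:
    """Strand-aware nucleosome-depleted promoter windows.

    The window covers [-upstream, +downstream) relative to the TSS in
    the direction of transcription: [tss-300, tss+100) on +, mirrored
    on - (same 400 bp width).
    """
    out = []
    for chrom, pos, strand in tss:
        if strand == "+":
            out.append((chrom, pos - upstream, pos + downstream))
        elif strand == "-":
            out.append((chrom, pos - downstream + 1, pos + upstream + 1))
        else:
            raise ValueError(f"bad strand {strand!r} for TSS at {chrom}:{pos}")
    return out


def count_promoter_inserts(
    inserts: dict[str, list[tuple[str, int]]],
    tss: list[tuple[str, int, str]],
    upstream: int = 300,
    downstream: int = 100,
) -> dict[str, int]:
    """Per-sample count of insert positions falling in any promoter window."""
    windows = promoter_windows(tss, upstream, downstream)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in windows:
        by_chrom.setdefault(chrom, []).append((s, e))
    # collapse overlapping windows so an insert is counted once
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out: list[tuple[int, int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[chrom] = out
    totals: dict[str, int] = {}
    for sample, positions in inserts.items():
        count = 0
        for chrom, pos in positions:
            for s, e in merged.get(chrom, ()):
                if s <= pos < e:
                    count += 1
                    break
        totals[sample] = count
    return totals


def promoter_insert_normalization(
    counts: pd.DataFrame,
    promoter_totals: dict[str, int] | None = None,
    inserts: dict[str, list[tuple[str, int]]] | None = None,
    tss: list[tuple[str, int, str]] | None = None,
) -> pd.DataFrame:
    """Normalize a peak-by-sample count matrix by promoter insert totals.

    Each sample's column is divided by that sample's promoter-insert
    total and rescaled by the across-sample mean total, keeping values
    in count-like units. Supply either precomputed ``promoter_totals``
    or raw ``inserts`` plus ``tss`` positions.
    """
    if promoter_totals is None:
        if inserts is None or tss is None:
            raise ValueError("supply promoter_totals, or inserts and tss")
        promoter_totals = count_promoter_inserts(inserts, tss)
    missing = [c for c in counts.columns if c not in promoter_totals]
    if missing:
        raise ValueError(f"no promoter totals for samples: {missing}")
    totals = np.array([promoter_totals[c] for c in counts.columns], dtype=float)
    if np.any(totals <= 0):
        bad = [c for c, t in zip(counts.columns, totals) if t <= 0]
        raise ValueError(f"zero promoter inserts in samples: {bad}")
    scale = totals.mean() / totals
    return counts * scale
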