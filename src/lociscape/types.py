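"""Core domain records shared across the analysis stages.

Coordinates are 0-based half-open throughout the library; GTF input
(1-based, end-inclusive) is converted on read by :mod:`lociscape.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class TranscriptRecord:
    """One assembled transcript with its genomic span and expression.

    ``mature_length`` is the summed exon length (the spliced transcript
    length), which can be shorter than the genomic span ``end - start``
    for multi-exonic transcripts.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    exon_blocks: tuple[tuple[int, int], ...]
    expression: float
    expression_tpm: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"transcript {self.id}: end must exceed start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.id}: strand must be '+' or '-'")
        if self.expression < 0:
            raise ValueError(f"transcript {self.id}: expression must be >= 0")
        if not self.exon_blocks:
            raise ValueError(f"transcript {self.id}: at least one exon required")
        prev_end = None
        for (s, e) in self.exon_blocks:
            if e <= s:
                raise ValueError(f"transcript {self.id}: empty exon block ({s},{e})")
            if s < self.start or e > self.end:
                raise ValueError(f"transcript {self.id}: exon outside span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"transcript {self.id}: exons overlap or unsorted")
            prev_end = e

    @property
    def mature_length(self) -> int:
        return sum(e - s for s, e in self.exon_blocks)

    @property
    def n_exons(self) -> int:
        return len(self.exon_blocks)

    @property
    def five_prime(self) -> int:
        """5'-most genomic coordinate: start for +, end-1 for -."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class GeneSegment:
    """A gene segment (e.g. a VH element) with a recombination-usage flag."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    used_in_recombination: bool

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"segment {self.id}: end must exceed start")


@dataclass
class PeakRecord:
    """One called peak; ``score_raw`` holds the caller's -log10(p)."""

    chrom: str
    start: int
    end: int
    score_raw: float
    sample_id: str
    name: str = "."
    spm: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("peak: end must exceed start")
        if self.score_raw < 0:
            raise ValueError("peak: score must be >= 0")

    def overlaps(self, other: "PeakRecord") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end
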