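from __future__ import annotations

import numpy as np
import pytest

from lociscape.types import TranscriptRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_transcript(
    tid="t1",
    chrom="chr1",
    start=0,
    end=None,
    strand="+",
    exons=None,
    fpkm=1.0,
    tpm=None,
    length=1000,
):
    """Build a TranscriptRecord with sensible defaults: mono-exonic of
    the given mature length unless explicit exons are supplied."""
    if exons is None:
        end = start + length if end is None else end
        exons = ((start, end),)
    else:
        end = exons[-1][1] if end is None else end
    return TranscriptRecord(
        id=tid,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        exon_blocks=tuple(exons),
        expression=fpkm,
        expression_tpm=tpm,
    )


@pytest.fixture
def transcript_factory():
    return make_transcript


def random_transcripts(rng, n, chrom_sizes, max_len=5000):
    """Random mono/multi-exonic transcripts across the given chromosomes."""
    out = []
    chroms = list(chrom_sizes)
    for k in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        size = chrom_sizes[chrom]
        length = int(rng.integers(60, max_len))
        start = int(rng.integers(0, size - 3 * length))
        strand = "+" if rng.random() < 0.5 else "-"
        if rng.random() < 0.3:
            gap = int(rng.integers(1, length))
            half = length // 2
            exons = ((start, start + half), (start + half + gap, start + length + gap))
        else:
            exons = ((start, start + length),)
        out.append(
            TranscriptRecord(
                id=f"r{k}",
                chrom=chrom,
                start=exons[0][0],
                end=exons[-1][1],
                strand=strand,
                exon_blocks=exons,
                expression=float(rng.uniform(0, 5)),
            )
        )
    return out
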