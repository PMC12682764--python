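"""Synthetic data with the statistical structure the pipeline assumes.

Three generators produce desk-scale stand-ins for the real inputs:

* a transcriptome with background transcripts at uniform genomic
  density (log-normal lengths and expression) plus one planted locus
  with elevated density and expression — the structure behind a
  top-ranked enrichment window;
* intrachromosomal contact matrices with power-law distance decay,
  Poisson counting noise, and planted anchor enrichments — the
  structure behind virtual-4C interaction calls; an optional
  bin-visibility bias (shared between replicates via its own seed)
  emulates mappability/restriction-site heterogeneity;
* replicate peak sets sharing true peaks (with dropout) plus
  sample-specific noise peaks — the structure behind the
  reproducibility filter.

All generators are deterministic for a fixed config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .contacts import ContactMatrix
from .types import PeakRecord, TranscriptRecord


def _default_chrom_sizes() -> dict[str, int]:
    return {f"chr{i}": 50_000_000 for i in range(1, 6)}


@dataclass
class TranscriptomeSimConfig:
    """Study conditions for the transcriptome generator.

    Densities are transcripts per Mb; the planted locus multiplies both
    transcript density and expression inside its interval. Length and
    expression are log-normal: ``length_dist`` defaults to a ~1 kb
    median mature length and ``expr_dist`` to a ~1 FPKM median.
    """

    chrom_sizes: dict[str, int] = field(default_factory=_default_chrom_sizes)
    background_density: float = 0.5
    planted_locus: tuple[str, int, int] | None = ("chr1", 20_000_000, 23_000_000)
    planted_multiplier: float = 40.0
    length_dist: tuple[float, float] = (6.9, 0.6)  # (mean-log, sd-log), bp
    expr_dist: tuple[float, float] = (0.0, 1.0)  # (mean-log, sd-log), FPKM
    planted_expr_multiplier: float = 5.0
    multi_exon_prob: float = 0.10
    antisense_prob: float = 0.45
    seed: int = 0
    max_expected_transcripts: int = 1_000_000

    def __post_init__(self) -> None:
        if self.background_density < 0:
            raise ValueError("background_density must be >= 0")
        if self.planted_multiplier < 1 or self.planted_expr_multiplier < 1:
            raise ValueError("planted multipliers must be >= 1")
        for p in (self.multi_exon_prob, self.antisense_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.planted_locus is not None:
            chrom, s, e = self.planted_locus
            if chrom not in self.chrom_sizes:
                raise ValueError(f"planted locus chromosome {chrom} unknown")
            if not (0 <= s < e <= self.chrom_sizes[chrom]):
                raise ValueError("planted locus must lie within its chromosome")

    def expected_transcripts(self) -> float:
        total = sum(self.chrom_sizes.values()) / 1e6 * self.background_density
        if self.planted_locus is not None:
            _, s, e = self.planted_locus
            total += (e - s) / 1e6 * self.background_density * (
                self.planted_multiplier - 1
            )
        return total


def simulate_transcriptome(cfg: TranscriptomeSimConfig) -> list[TranscriptRecord]:
    """Draw a transcript set under ``cfg``.

    Transcript counts per region are Poisson with mean density x length
    (x multiplier inside the planted locus); positions are uniform.
    Mature length is log-normal floored at 50 bp; mono-exonic
    transcripts have genomic span equal to mature length, multi-exonic
    ones (2-6 exons) have introns inflating the span by a uniform 1-5x
    factor. Expression is log-normal, scaled by the planted expression
    multiplier for transcripts starting inside the planted locus.
    """
    if cfg.expected_transcripts() > cfg.max_expected_transcripts:
        raise ValueError(
            f"expected transcript count {cfg.expected_transcripts():.0f} exceeds "
            f"cap {cfg.max_expected_transcripts}; lower the density or raise the cap"
        )
    rng = np.random.default_rng(cfg.seed)
    records: list[TranscriptRecord] = []
    counter = 0
    for chrom in cfg.chrom_sizes:
        size = cfg.chrom_sizes[chrom]
        n_bg = rng.poisson(cfg.background_density * size / 1e6)
        starts = np.sort(rng.integers(0, size, size=n_bg))
        for pos in starts:
            counter += 1
            records.append(_draw_transcript(rng, cfg, chrom, int(pos), counter))
        if cfg.planted_locus is not None and cfg.planted_locus[0] == chrom:
            _, ls, le = cfg.planted_locus
            extra_rate = (
                cfg.background_density * (cfg.planted_multiplier - 1) * (le - ls) / 1e6
            )
            n_extra = rng.poisson(extra_rate)
            extra_starts = np.sort(rng.integers(ls, le, size=n_extra))
            for pos in extra_starts:
                counter += 1
                records.append(_draw_transcript(rng, cfg, chrom, int(pos), counter))
    return records


def _draw_transcript(
    rng: np.random.Generator,
    cfg: TranscriptomeSimConfig,
    chrom: str,
    pos: int,
    counter: int,
) -> TranscriptRecord:
    size = cfg.chrom_sizes[chrom]
    mature = max(50, int(round(rng.lognormal(*cfg.length_dist))))
    mature = min(mature, size - 1)
    expr = float(rng.lognormal(*cfg.expr_dist))
    multi = rng.random() < cfg.multi_exon_prob
    strand = "-" if rng.random() < cfg.antisense_prob else "+"
    if multi:
        n_exons = int(rng.integers(2, 7))
        n_exons = min(n_exons, mature)  # every exon needs >= 1 bp
        span = int(round(mature * rng.uniform(1.0, 5.0)))
        span = max(span, mature + n_exons - 1)  # every intron needs >= 1 bp
        span = min(span, size)
    else:
        n_exons = 1
        span = mature
    start = min(pos, size - span)
    end = start + span
    if n_exons == 1:
        blocks = ((start, end),)
    else:
        exon_lens = _random_composition(rng, mature, n_exons)
        intron_lens = _random_composition(rng, span - mature, n_exons - 1)
        blocks_list = []
        cursor = start
        for i, el in enumerate(exon_lens):
            blocks_list.append((cursor, cursor + el))
            cursor += el
            if i < n_exons - 1:
                cursor += intron_lens[i]
        blocks = tuple(blocks_list)
    in_locus = (
        cfg.planted_locus is not None
        and cfg.planted_locus[0] == chrom
        and cfg.planted_locus[1] <= start < cfg.planted_locus[2]
    )
    if in_locus:
        expr *= cfg.planted_expr_multiplier
    return TranscriptRecord(
        id=f"SIM.{counter}",
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        exon_blocks=blocks,
        expression=expr,
    )


def _random_composition(rng: np.random.Generator, total: int, parts: int) -> list[int]:
    """Split ``total`` into ``parts`` positive integers, uniformly over
    compositions (stars and bars via sorted distinct cut points)."""
    if parts == 1:
        return [total]
    cuts = np.sort(rng.choice(total - 1, size=parts - 1, replace=False)) + 1
    bounds = np.concatenate([[0], cuts, [total]])
    return list(np.diff(bounds).astype(int))


def simulate_gene_segments(
    cfg: TranscriptomeSimConfig,
    n_segments: int = 180,
    used_fraction: float = 0.8,
    segment_length: int = 500,
) -> list["GeneSegment"]:
    """Place gene segments (VH-like, default 180 with 80% usage) at
    uniform non-overlapping positions inside the planted locus (or the
    first chromosome when no locus is planted). Uses ``cfg.seed + 1``
    so segments are stable against re-draws of the transcriptome."""
    from .types import GeneSegment

    rng = np.random.default_rng(cfg.seed + 1)
    if cfg.planted_locus is not None:
        chrom, lo, hi = cfg.planted_locus
    else:
        chrom = next(iter(cfg.chrom_sizes))
        lo, hi = 0, cfg.chrom_sizes[chrom]
    slot = (hi - lo) // max(n_segments, 1)
    if slot <= segment_length:
        raise ValueError("locus too small for the requested segment count")
    used = rng.random(n_segments) < used_fraction
    segments = []
    for k in range(n_segments):
        off = int(rng.integers(0, slot - segment_length))
        start = lo + k * slot + off
        segments.append(
            GeneSegment(
                id=f"VH_{k + 1}",
                chrom=chrom,
                start=start,
                end=start + segment_length,
                strand="-",
                used_in_recombination=bool(used[k]),
            )
        )
    return segments


@dataclass
class ContactSimConfig:
    """Study conditions for the contact-matrix generator.

    Expected count at bin distance d is
    ``base_intensity * (1 + d)^-decay_exponent``, multiplied by the
    planted fold at planted pairs (symmetrically) and by bin visibility
    biases b_i * b_j when ``bias_sdlog > 0``. Biases draw from their own
    ``bias_seed`` so replicates simulated with different ``seed`` values
    share the same underlying structure.
    """

    n_bins: int = 300
    bin_size: int = 10_000
    decay_exponent: float = 1.0
    base_intensity: float = 100.0
    planted_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    seed: int = 0
    chrom: str = "chrSim"
    bias_sdlog: float = 0.0
    bias_seed: int = 777

    def __post_init__(self) -> None:
        if self.n_bins < 10:
            raise ValueError("n_bins must be >= 10")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if self.base_intensity < 0:
            raise ValueError("base_intensity must be >= 0")
        if self.bias_sdlog < 0:
            raise ValueError("bias_sdlog must be >= 0")
        for i, j, fold in self.planted_pairs:
            if not (0 <= i < self.n_bins and 0 <= j < self.n_bins):
                raise ValueError(f"planted pair ({i},{j}) outside matrix bounds")
            if fold < 1:
                raise ValueError("planted fold must be >= 1")


def simulate_contacts(cfg: ContactSimConfig) -> ContactMatrix:
    """Sample a symmetric Poisson contact matrix under ``cfg``."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_bins
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    lam = cfg.base_intensity * (1.0 + d) ** (-cfg.decay_exponent)
    if cfg.bias_sdlog > 0:
        bias_rng = np.random.default_rng(cfg.bias_seed)
        b = bias_rng.lognormal(-cfg.bias_sdlog**2 / 2, cfg.bias_sdlog, size=n)
        lam = lam * np.outer(b, b)
    fold = np.ones((n, n))
    for i, j, f in cfg.planted_pairs:
        fold[i, j] = max(fold[i, j], f)
        fold[j, i] = max(fold[j, i], f)
    lam = lam * fold
    iu = np.triu_indices(n)
    upper = rng.poisson(lam[iu]).astype(float)
    counts = np.zeros((n, n))
    counts[iu] = upper
    counts.T[iu] = upper
    return ContactMatrix(
        region=(cfg.chrom, 0, n * cfg.bin_size),
        bin_size=cfg.bin_size,
        counts=counts,
        balanced=False,
    )


def simulate_replicates(cfg: ContactSimConfig, n_replicates: int = 2) -> list[ContactMatrix]:
    """Independent Poisson draws of the same expected structure; the
    k-th replicate uses ``cfg.seed + k`` while sharing ``bias_seed``."""
    return [
        simulate_contacts(replace(cfg, seed=cfg.seed + k)) for k in range(n_replicates)
    ]


@dataclass
class PeakSimConfig:
    """Study conditions for the replicate peak-set generator.

    True peaks occupy fixed intervals shared across samples; each
    appears in a sample with probability 1 - dropout_prob (position
    jittered by at most ``jitter_bp``, default 0). Noise peaks are
    sample-specific and never overlap true peaks or each other, so the
    ground truth for the reproducibility filter is unambiguous.
    ``score_dist`` gives gamma (shape, scale) for -log10(p) scores.
    """

    n_true_peaks: int = 100
    n_samples: int = 3
    noise_peaks_per_sample: int = 20
    score_dist: tuple[float, float] = (2.0, 10.0)
    dropout_prob: float = 0.2
    jitter_bp: int = 0
    seed: int = 0
    chrom: str = "chr1"
    slot_bp: int = 2_000
    peak_width: tuple[int, int] = (200, 500)

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_true_peaks < 0 or self.noise_peaks_per_sample < 0:
            raise ValueError("peak counts must be >= 0")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must lie in [0, 1]")
        if self.jitter_bp < 0:
            raise ValueError("jitter_bp must be >= 0")


@dataclass
class PeakSimResult:
    samples: dict[str, list[PeakRecord]]
    truth: pd.DataFrame  # peak_id, chrom, start, end, kind, samples_present


def simulate_peak_samples(cfg: PeakSimConfig) -> PeakSimResult:
    """Draw replicate peak sets plus a ground-truth manifest.

    Intervals are placed on a slot grid (one peak per slot, slots wide
    enough that jittered peaks cannot collide) with slot indices drawn
    without replacement, so no two generated peaks ever overlap unless
    they are the same true peak seen in different samples.
    """
    rng = np.random.default_rng(cfg.seed)
    n_noise_total = cfg.n_samples * cfg.noise_peaks_per_sample
    n_slots_needed = cfg.n_true_peaks + n_noise_total
    n_slots = max(4 * n_slots_needed, 100)
    slot_ids = rng.choice(n_slots, size=n_slots_needed, replace=False)
    widths = rng.integers(
        cfg.peak_width[0], cfg.peak_width[1] + 1, size=n_slots_needed
    )
    margin = cfg.jitter_bp
    starts = slot_ids * cfg.slot_bp + margin
    true_iv = [
        (int(starts[k]), int(starts[k] + widths[k])) for k in range(cfg.n_true_peaks)
    ]
    noise_iv = [
        (int(starts[k]), int(starts[k] + widths[k]))
        for k in range(cfg.n_true_peaks, n_slots_needed)
    ]
    sample_ids = [f"S{i + 1}" for i in range(cfg.n_samples)]
    samples: dict[str, list[PeakRecord]] = {s: [] for s in sample_ids}
    presence: dict[int, list[str]] = {k: [] for k in range(cfg.n_true_peaks)}
    for si, sample in enumerate(sample_ids):
        for k, (s, e) in enumerate(true_iv):
            if rng.random() < cfg.dropout_prob:
                continue
            presence[k].append(sample)
            off = int(rng.integers(-cfg.jitter_bp, cfg.jitter_bp + 1)) if cfg.jitter_bp else 0
            score = float(rng.gamma(*cfg.score_dist))
            samples[sample].append(
                PeakRecord(
                    chrom=cfg.chrom,
                    start=s + off,
                    end=e + off,
                    score_raw=score,
                    sample_id=sample,
                    name=f"true_{k}",
                )
            )
        lo = cfg.n_true_peaks + si * cfg.noise_peaks_per_sample
        for k in range(cfg.noise_peaks_per_sample):
            s, e = noise_iv[si * cfg.noise_peaks_per_sample + k]
            score = float(rng.gamma(*cfg.score_dist))
            samples[sample].append(
                PeakRecord(
                    chrom=cfg.chrom,
                    start=s,
                    end=e,
                    score_raw=score,
                    sample_id=sample,
                    name=f"noise_{sample}_{k}",
                )
            )
    for sample in sample_ids:
        samples[sample].sort(key=lambda p: (p.chrom, p.start))
    rows = []
    for k, (s, e) in enumerate(true_iv):
        rows.append(
            {
                "peak_id": f"true_{k}",
                "chrom": cfg.chrom,
                "start": s,
                "end": e,
                "kind": "true",
                "samples_present": ",".join(presence[k]),
                "n_samples_present": len(presence[k]),
            }
        )
    for si, sample in enumerate(sample_ids):
        for k in range(cfg.noise_peaks_per_sample):
            s, e = noise_iv[si * cfg.noise_peaks_per_sample + k]
            rows.append(
                {
                    "peak_id": f"noise_{sample}_{k}",
                    "chrom": cfg.chrom,
                    "start": s,
                    "end": e,
                    "kind": "noise",
                    "samples_present": sample,
                    "n_samples_present": 1,
                }
            )
    truth = pd.DataFrame(rows)
    return PeakSimResult(samples=samples, truth=truth)
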