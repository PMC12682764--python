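"""End-to-end orchestration: simulate -> rank -> features -> v4c -> atac.

A :class:`RunConfig` (YAML-loadable) toggles stages and carries every
stage parameter. Each stage writes its outputs plus a ``manifest.json``
(parameters, input hashes, package version) into its own subdirectory;
the run ends with a combined Markdown/TSV report relating the locus of
interest's window rank, lncRNA feature tallies, and replicate-
intersected interaction calls. Outputs are fully determined by config
and seed; the report body contains no timestamps so identical runs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, contacts, features, io, peaks, synthetic, windows

log = logging.getLogger("lociscape")

STAGE_ORDER = ("simulate", "rank", "features", "v4c", "atac")


@dataclass
class RunConfig:
    """All pipeline inputs, stage toggles and parameters."""

    out_dir: str = "lociscape_run"
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGE_ORDER}
    )

    # window ranking
    bin_size: int = 100_000
    max_gap_bins: int = 2
    min_length: int = 300
    min_fpkm: float = 0.3
    score_mode: str = "rank_sum"
    bin_assignment: str = "five_prime"
    locus: tuple[str, int, int] | None = None  # defaults to the simulated locus

    # feature classification
    reference_strand: str = "-"
    proximity_bp: int = 500

    # contact maps
    v4c_fraction: float = 0.15
    v4c_window_bp: int = 30_000
    scc_threshold: float = 0.9
    viewpoint: int | None = None  # genomic position; defaults to simulated viewpoint

    # ATAC
    min_samples: int = 2
    min_spm: float = 2.0

    # external inputs (used when the simulate stage is off)
    gtf: str | None = None
    chrom_sizes: str | None = None
    annotation: str | None = None
    segments: str | None = None
    matrix_replicates: list[tuple[str, str]] = field(default_factory=list)  # (matrix, bins)
    peak_files: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "locus" in raw and raw["locus"] is not None:
            raw["locus"] = tuple(raw["locus"])
        if "matrix_replicates" in raw:
            raw["matrix_replicates"] = [tuple(m) for m in raw["matrix_replicates"]]
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(stage_dir: Path, params: dict, inputs: list[Path]) -> None:
    manifest = {
        "version": __version__,
        "parameters": params,
        "inputs": {str(p): _sha256(p) for p in inputs if p is not None and Path(p).exists()},
    }
    with open(stage_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


# default simulated-contact geometry: viewpoint mid-matrix, anchors at
# enhancer-hub spacings (150-400 kb at 10 kb bins)
V4C_VIEWPOINT_BIN = 150
V4C_ANCHOR_OFFSETS = (-40, -25, 15, 28, 40)
V4C_ANCHOR_FOLD = 8.0


def default_contact_config(seed: int) -> synthetic.ContactSimConfig:
    pairs = [
        (V4C_VIEWPOINT_BIN, V4C_VIEWPOINT_BIN + o, V4C_ANCHOR_FOLD)
        for o in V4C_ANCHOR_OFFSETS
    ]
    # visibility bias on: pipeline replicates should behave like real
    # replicate libraries (shared structure, SCC above the merge gate)
    return synthetic.ContactSimConfig(seed=seed, planted_pairs=pairs, bias_sdlog=0.35)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns a result
    bundle with per-stage outputs and the report path."""
    out = io.ensure_dir(config.out_dir)
    enabled = [s for s in STAGE_ORDER if config.stages.get(s, False)]
    results: dict = {"out_dir": str(out), "stages_run": enabled}
    state: dict = {}
    for stage in enabled:
        stage_dir = io.ensure_dir(out / stage)
        try:
            log.info("running stage %s", stage)
            _STAGES[stage](config, stage_dir, state)
        except Exception as exc:  # noqa: BLE001 - report stage then abort
            (stage_dir / "FAILED").write_text(f"stage {stage}: {exc}\n")
            raise StageError(stage, exc) from exc
    report_path = _write_report(config, out, state)
    results["report"] = str(report_path)
    results.update(state.get("summary", {}))
    return results


def _stage_simulate(config: RunConfig, stage_dir: Path, state: dict) -> None:
    tcfg = synthetic.TranscriptomeSimConfig(seed=config.seed)
    records = synthetic.simulate_transcriptome(tcfg)
    gtf = stage_dir / "transcripts.gtf"
    io.write_gtf_transcripts(records, gtf, header=f"seed={config.seed}")
    sizes = stage_dir / "chrom.sizes"
    io.write_chrom_sizes(tcfg.chrom_sizes, sizes)
    segs = synthetic.simulate_gene_segments(tcfg)
    seg_path = stage_dir / "segments.bed"
    io.write_segments(segs, seg_path)

    ccfg = default_contact_config(config.seed)
    reps = synthetic.simulate_replicates(ccfg)
    matrix_paths = []
    for i, m in enumerate(reps, start=1):
        mp = stage_dir / f"contacts_rep{i}.tsv"
        bp = stage_dir / f"contacts_rep{i}.bins.tsv"
        io.write_contact_matrix_sparse(m, mp, bp)
        matrix_paths.append((str(mp), str(bp)))

    pcfg = synthetic.PeakSimConfig(seed=config.seed)
    sim_peaks = synthetic.simulate_peak_samples(pcfg)
    peak_paths = []
    for sample, plist in sim_peaks.samples.items():
        pp = stage_dir / f"atac_{sample}.narrowPeak"
        io.write_narrowpeak(plist, pp)
        peak_paths.append(str(pp))
    sim_peaks.truth.to_csv(stage_dir / "peak_truth.tsv", sep="\t", index=False)

    state["transcripts"] = records
    state["chrom_sizes"] = tcfg.chrom_sizes
    state["segments"] = segs
    state["contact_replicates"] = reps
    state["contact_config"] = ccfg
    state["peak_samples"] = sim_peaks.samples
    state["peak_truth"] = sim_peaks.truth
    state["sim_locus"] = tcfg.planted_locus
    _write_manifest(
        stage_dir,
        {"seed": config.seed, "transcriptome": dataclasses.asdict(tcfg),
         "contacts": dataclasses.asdict(ccfg), "peaks": dataclasses.asdict(pcfg)},
        [gtf, sizes, seg_path],
    )


def _stage_rank(config: RunConfig, stage_dir: Path, state: dict) -> None:
    if "transcripts" in state:
        records = state["transcripts"]
        chrom_sizes = state["chrom_sizes"]
    else:
        if not config.gtf or not config.chrom_sizes:
            raise ValueError("rank stage needs gtf and chrom_sizes inputs")
        records = io.read_gtf_transcripts(config.gtf)
        chrom_sizes = io.read_chrom_sizes(config.chrom_sizes)
    annotation = None
    if config.annotation:
        ann = io.read_gtf_transcripts(config.annotation)
        annotation = [(t.chrom, s, e) for t in ann for (s, e) in t.exon_blocks]
    kept = windows.filter_transcripts(
        records, min_length=config.min_length, min_fpkm=config.min_fpkm,
        known_annotation=annotation,
    )
    binning = windows.GenomeBinning(chrom_sizes, bin_size=config.bin_size)
    stats = windows.compute_bin_stats(kept, binning, assignment=config.bin_assignment)
    wins = windows.merge_windows(stats, max_gap_bins=config.max_gap_bins, binning=binning)
    wins = windows.score_and_rank(wins, score_mode=config.score_mode)
    io.write_windows_tsv(wins, stage_dir / "windows.tsv")
    io.write_windows_bed(wins, stage_dir / "windows.bed")
    locus = config.locus or state.get("sim_locus")
    report = windows.locate_locus(wins, locus) if locus else None
    state["windows"] = wins
    state["filtered_transcripts"] = kept
    state["locus_report"] = report
    state["locus"] = locus
    _write_manifest(
        stage_dir,
        {"bin_size": config.bin_size, "max_gap_bins": config.max_gap_bins,
         "min_length": config.min_length, "min_fpkm": config.min_fpkm,
         "score_mode": config.score_mode, "locus": locus,
         "n_transcripts_in": len(records), "n_transcripts_kept": len(kept)},
        [Path(p) for p in (config.gtf, config.chrom_sizes) if p],
    )


def _stage_features(config: RunConfig, stage_dir: Path, state: dict) -> None:
    if "filtered_transcripts" in state:
        transcripts = state["filtered_transcripts"]
    elif config.gtf:
        transcripts = windows.filter_transcripts(
            io.read_gtf_transcripts(config.gtf),
            min_length=config.min_length, min_fpkm=config.min_fpkm,
        )
    else:
        raise ValueError("features stage needs transcripts (simulate stage or gtf)")
    if "segments" in state:
        segs = state["segments"]
    elif config.segments:
        segs = io.read_segments(config.segments)
    else:
        raise ValueError("features stage needs segments (simulate stage or segments file)")
    calls = features.classify_features(
        transcripts, segs,
        reference_strand=config.reference_strand, proximity_bp=config.proximity_bp,
    )
    rows = [
        {
            "transcript_id": c.transcript_id,
            "exonic_class": c.exonic_class,
            "orientation": c.orientation,
            "overlapping_segments": ",".join(c.overlapping_segments),
            "proximal_segments": ",".join(f"{s}:{d}" for s, d in c.proximal_segments),
        }
        for c in calls
    ]
    import pandas as pd

    pd.DataFrame(rows).to_csv(stage_dir / "feature_calls.tsv", sep="\t", index=False)
    assoc = features.usage_association(calls, segs)
    pd.DataFrame(
        [{
            "overlapped_used": assoc.overlapped_used,
            "overlapped_unused": assoc.overlapped_unused,
            "not_overlapped_used": assoc.not_overlapped_used,
            "not_overlapped_unused": assoc.not_overlapped_unused,
            "odds_ratio": assoc.odds_ratio,
            "fisher_p": assoc.fisher_p,
        }]
    ).to_csv(stage_dir / "usage_association.tsv", sep="\t", index=False)
    mono = [t.expression_tpm if t.expression_tpm is not None else t.expression
            for t in transcripts if t.n_exons == 1]
    multi = [t.expression_tpm if t.expression_tpm is not None else t.expression
             for t in transcripts if t.n_exons >= 2]
    expr_cmp = None
    if mono and multi:
        expr_cmp = features.compare_expression(mono, multi)
        pd.DataFrame([expr_cmp]).to_csv(
            stage_dir / "expression_comparison.tsv", sep="\t", index=False
        )
    state["feature_calls"] = calls
    state["usage_association"] = assoc
    state["expression_comparison"] = expr_cmp
    _write_manifest(
        stage_dir,
        {"reference_strand": config.reference_strand,
         "proximity_bp": config.proximity_bp, "n_transcripts": len(transcripts),
         "n_segments": len(segs)},
        [Path(config.segments)] if config.segments else [],
    )


def _stage_v4c(config: RunConfig, stage_dir: Path, state: dict) -> None:
    if "contact_replicates" in state:
        reps = state["contact_replicates"]
        viewpoint = config.viewpoint
        if viewpoint is None:
            viewpoint = V4C_VIEWPOINT_BIN * reps[0].bin_size + 1
    else:
        if not config.matrix_replicates:
            raise ValueError("v4c stage needs contact matrices")
        reps = [io.read_contact_matrix(m, b) for m, b in config.matrix_replicates]
        viewpoint = config.viewpoint
        if viewpoint is None:
            raise ValueError("v4c stage needs a viewpoint position")
    concordance = None
    if len(reps) >= 2:
        concordance = contacts.scc(reps[0], reps[1])
        merged = contacts.merge_replicates(
            reps[0], reps[1], scc_threshold=config.scc_threshold
        ) if concordance.scc >= config.scc_threshold else None
    balanced = [contacts.balance(m) for m in reps]
    profiles = [
        contacts.virtual_4c(
            b, viewpoint, window_bp=config.v4c_window_bp, fraction=config.v4c_fraction
        )
        for b in balanced
    ]
    calls = contacts.call_top_interactions(profiles, fraction=config.v4c_fraction)
    chrom, rstart, _ = reps[0].region
    for i, p in enumerate(profiles, start=1):
        io.write_bedgraph(
            stage_dir / f"v4c_rep{i}.bedGraph", chrom, rstart, reps[0].bin_size,
            p.values, track_name=f"v4c_rep{i}",
        )
    with open(stage_dir / "calls_intersection.bed", "w") as fh:
        for b in sorted(calls.intersection):
            s = rstart + b * reps[0].bin_size
            fh.write(f"{chrom}\t{s}\t{s + reps[0].bin_size}\tcall\n")
    state["v4c_profiles"] = profiles
    state["v4c_calls"] = calls
    state["v4c_viewpoint"] = viewpoint
    state["scc"] = concordance
    _write_manifest(
        stage_dir,
        {"viewpoint": viewpoint, "fraction": config.v4c_fraction,
         "window_bp": config.v4c_window_bp, "scc_threshold": config.scc_threshold,
         "scc": concordance.scc if concordance else None},
        [Path(m) for m, _ in config.matrix_replicates],
    )


def _stage_atac(config: RunConfig, stage_dir: Path, state: dict) -> None:
    if "peak_samples" in state:
        samples = state["peak_samples"]
    elif config.peak_files:
        samples = {
            f"S{i + 1}": io.read_narrowpeak(p, f"S{i + 1}")
            for i, p in enumerate(config.peak_files)
        }
    else:
        raise ValueError("atac stage needs peak files (simulate stage or peak_files)")
    for plist in samples.values():
        peaks.to_spm(plist)
    merged = peaks.merge_peak_sets(list(samples.values()))
    filtered = peaks.reproducibility_filter(
        merged, min_samples=config.min_samples, min_spm=config.min_spm
    )
    import pandas as pd

    rows = [
        {
            "chrom": p.chrom, "start": p.start, "end": p.end, "spm": p.spm,
            "n_samples": len(p.support),
            "support": ",".join(f"{s}:{v:.2f}" for s, v in sorted(p.support.items())),
        }
        for p in filtered.peaks
    ]
    pd.DataFrame(rows).to_csv(stage_dir / "consensus_peaks.tsv", sep="\t", index=False)
    state["consensus_peaks"] = filtered
    state["n_peaks_prefilter"] = len(merged)
    _write_manifest(
        stage_dir,
        {"min_samples": config.min_samples, "min_spm": config.min_spm,
         "n_samples": len(samples), "n_consensus": len(filtered),
         "n_prefilter": len(merged)},
        [Path(p) for p in config.peak_files],
    )


_STAGES = {
    "simulate": _stage_simulate,
    "rank": _stage_rank,
    "features": _stage_features,
    "v4c": _stage_v4c,
    "atac": _stage_atac,
}


def _write_report(config: RunConfig, out: Path, state: dict) -> Path:
    lines = ["# lociscape run report", ""]
    summary: dict = {}
    rep = state.get("locus_report")
    if rep is not None:
        chrom, s, e = rep.locus
        lines += [
            "## Locus window rank",
            "",
            f"- locus: {chrom}:{s}-{e}",
            f"- best overlapping window rank: {rep.best_rank} "
            f"of {state['windows'][0].n_windows_total}",
            f"- single window: {rep.single_window}",
            "",
        ]
        summary["locus_best_rank"] = rep.best_rank
        summary["locus_single_window"] = rep.single_window
    calls = state.get("feature_calls")
    if calls is not None:
        mono = sum(1 for c in calls if c.exonic_class == "mono")
        multi = len(calls) - mono
        anti = sum(1 for c in calls if c.orientation == "antisense")
        assoc = state.get("usage_association")
        lines += [
            "## lncRNA features",
            "",
            f"- transcripts: {len(calls)} (mono-exonic {mono}, multi-exonic {multi})",
            f"- antisense: {anti}/{len(calls)}",
        ]
        if assoc is not None:
            lines += [
                f"- segment overlap x usage odds ratio: {assoc.odds_ratio:.3f} "
                f"(Fisher p={assoc.fisher_p:.3g})",
            ]
        lines += [""]
        summary["n_feature_calls"] = len(calls)
    v4c_calls = state.get("v4c_calls")
    if v4c_calls is not None:
        scc_res = state.get("scc")
        lines += [
            "## Virtual 4C",
            "",
            f"- replicate SCC: {scc_res.scc:.4f}" if scc_res else "- single replicate",
            f"- replicate-intersected calls: {len(v4c_calls.intersection)} bins",
            "",
        ]
        summary["n_v4c_calls"] = len(v4c_calls.intersection)
    cons = state.get("consensus_peaks")
    if cons is not None:
        lines += [
            "## ATAC consensus peaks",
            "",
            f"- reproducible peaks: {len(cons)} "
            f"(of {state.get('n_peaks_prefilter')} pre-filter)",
            "",
        ]
        summary["n_consensus_peaks"] = len(cons)
    if len(lines) == 2:
        lines += ["(no stages enabled)", ""]
    report_path = out / "report.md"
    report_path.write_text("\n".join(lines))
    state["summary"] = summary
    import pandas as pd

    pd.DataFrame([summary]).to_csv(out / "summary.tsv", sep="\t", index=False)
    return report_path
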