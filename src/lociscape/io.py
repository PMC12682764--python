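"""Readers and writers for the formats the pipeline consumes and emits.

GTF is 1-based end-inclusive on disk and converted to the library's
0-based half-open convention on read (and back on write). Expression is
read from transcript attributes (``FPKM``/``TPM``/``cov``; the primary
key is configurable). Contact matrices travel either as dense TSV with
a companion bin table or as sparse 3-column ``bin_i bin_j count`` dumps
with 0-based indices relative to the region start.
"""

from __future__ import annotations

import os
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

from .contacts import ContactMatrix
from .types import GeneSegment, PeakRecord, TranscriptRecord


# --- transcripts -----------------------------------------------------------

def read_gtf_transcripts(
    path: str | os.PathLike,
    expression_attr: str = "FPKM",
    tpm_attr: str = "TPM",
) -> list[TranscriptRecord]:
    """Load transcript models (transcript + exon features) from a GTF.

    Transcripts missing the expression attribute get expression 0;
    transcripts without exon features are treated as mono-exonic over
    their span.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    records: list[TranscriptRecord] = []
    for t in db.features_of_type("transcript"):
        exons = [
            (e.start - 1, e.end)
            for e in db.children(t, featuretype="exon", order_by="start")
        ]
        if not exons:
            exons = [(t.start - 1, t.end)]
        expr = float(t.attributes.get(expression_attr, ["0"])[0])
        tpm = t.attributes.get(tpm_attr)
        records.append(
            TranscriptRecord(
                id=t.id,
                chrom=t.seqid,
                start=t.start - 1,
                end=t.end,
                strand=t.strand if t.strand in "+-" else "+",
                exon_blocks=tuple(exons),
                expression=expr,
                expression_tpm=float(tpm[0]) if tpm else None,
            )
        )
    return records


def write_gtf_transcripts(
    records: list[TranscriptRecord],
    path: str | os.PathLike,
    source: str = "lociscape",
    header: str | None = None,
) -> None:
    """Write transcripts + exons as GTF with FPKM/TPM attributes."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for r in records:
            tpm = r.expression_tpm if r.expression_tpm is not None else r.expression
            attrs = (
                f'gene_id "{r.id}"; transcript_id "{r.id}"; '
                f'FPKM "{r.expression:.6f}"; TPM "{tpm:.6f}";'
            )
            fh.write(
                f"{r.chrom}\t{source}\ttranscript\t{r.start + 1}\t{r.end}\t.\t"
                f"{r.strand}\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(r.exon_blocks, start=1):
                fh.write(
                    f"{r.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{r.strand}\t.\t"
                    f'gene_id "{r.id}"; transcript_id "{r.id}"; exon_number "{i}";\n'
                )


# --- chromosome sizes ------------------------------------------------------

def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"],
                     usecols=[0, 1], comment="#")
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def write_chrom_sizes(sizes: dict[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# --- gene segments (BED6+1: column 7 = usage flag) -------------------------

def read_segments(path: str | os.PathLike) -> list[GeneSegment]:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand", "used"],
        usecols=range(7),
    )
    return [
        GeneSegment(
            id=str(row["name"]),
            chrom=str(row["chrom"]),
            start=int(row["start"]),
            end=int(row["end"]),
            strand=str(row["strand"]),
            used_in_recombination=bool(int(row["used"])),
        )
        for _, row in df.iterrows()
    ]


def write_segments(segments: list[GeneSegment], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.id}\t0\t{s.strand}\t"
                f"{int(s.used_in_recombination)}\n"
            )


# --- peaks (ENCODE narrowPeak) ---------------------------------------------

def read_narrowpeak(path: str | os.PathLike, sample_id: str) -> list[PeakRecord]:
    """Read a narrowPeak file; the score column (5) carries -log10(p)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand",
               "signalValue", "pValue", "qValue", "peak"],
    )
    return [
        PeakRecord(
            chrom=str(row["chrom"]),
            start=int(row["start"]),
            end=int(row["end"]),
            score_raw=float(row["score"]),
            sample_id=sample_id,
            name=str(row["name"]),
        )
        for _, row in df.iterrows()
    ]


def write_narrowpeak(peaks: list[PeakRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score_raw:.4f}\t.\t"
                f"{p.spm if p.spm is not None else 0:.4f}\t{p.score_raw:.4f}\t-1\t-1\n"
            )


# --- contact matrices ------------------------------------------------------

def write_contact_matrix_dense(
    matrix: ContactMatrix, matrix_path: str | os.PathLike, bins_path: str | os.PathLike
) -> None:
    np.savetxt(matrix_path, matrix.counts, delimiter="\t", fmt="%.6g")
    write_bin_table(matrix, bins_path)


def write_bin_table(matrix: ContactMatrix, path: str | os.PathLike) -> None:
    chrom, start, end = matrix.region
    rows = []
    for i in range(matrix.n_bins):
        bs = start + i * matrix.bin_size
        rows.append((chrom, bs, min(bs + matrix.bin_size, end), i))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "bin_index"]).to_csv(
        path, sep="\t", index=False
    )


def read_bin_table(path: str | os.PathLike) -> tuple[tuple[str, int, int], int, int]:
    """Return ((chrom, start, end), bin_size, n_bins) from a bin table."""
    df = pd.read_csv(path, sep="\t")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("bin table must cover one chromosome region")
    n = len(df)
    bin_size = int(df["end"].iloc[0] - df["start"].iloc[0]) if n == 1 else int(
        df["start"].iloc[1] - df["start"].iloc[0]
    )
    region = (str(chroms[0]), int(df["start"].min()), int(df["end"].max()))
    return region, bin_size, n


def read_contact_matrix_dense(
    matrix_path: str | os.PathLike, bins_path: str | os.PathLike
) -> ContactMatrix:
    counts = np.loadtxt(matrix_path, delimiter="\t", ndmin=2)
    region, bin_size, n = read_bin_table(bins_path)
    if counts.shape != (n, n):
        raise ValueError(
            f"matrix shape {counts.shape} does not match bin table ({n} bins)"
        )
    return ContactMatrix(region=region, bin_size=bin_size, counts=counts)


def write_contact_matrix_sparse(
    matrix: ContactMatrix, matrix_path: str | os.PathLike, bins_path: str | os.PathLike
) -> None:
    """Upper-triangle nonzero entries as ``bin_i bin_j count`` (0-based)."""
    iu = np.triu_indices(matrix.n_bins)
    vals = matrix.counts[iu]
    keep = np.isfinite(vals) & (vals != 0)
    df = pd.DataFrame(
        {"bin_i": iu[0][keep], "bin_j": iu[1][keep], "count": vals[keep]}
    )
    df.to_csv(matrix_path, sep="\t", index=False, header=False)
    write_bin_table(matrix, bins_path)


def read_contact_matrix_sparse(
    matrix_path: str | os.PathLike, bins_path: str | os.PathLike
) -> ContactMatrix:
    region, bin_size, n = read_bin_table(bins_path)
    df = pd.read_csv(
        matrix_path, sep="\t", header=None, names=["bin_i", "bin_j", "count"]
    )
    counts = np.zeros((n, n))
    i = df["bin_i"].to_numpy(dtype=int)
    j = df["bin_j"].to_numpy(dtype=int)
    if np.any((i < 0) | (i >= n) | (j < 0) | (j >= n)):
        raise ValueError("sparse dump contains bin indices outside the bin table")
    counts[i, j] = df["count"].to_numpy(dtype=float)
    counts[j, i] = df["count"].to_numpy(dtype=float)
    return ContactMatrix(region=region, bin_size=bin_size, counts=counts)


def read_contact_matrix(
    matrix_path: str | os.PathLike, bins_path: str | os.PathLike
) -> ContactMatrix:
    """Auto-detect dense vs sparse dialect by column count."""
    with open(matrix_path) as fh:
        first = fh.readline()
    if len(first.rstrip("\n").split("\t")) == 3:
        return read_contact_matrix_sparse(matrix_path, bins_path)
    return read_contact_matrix_dense(matrix_path, bins_path)


# --- track / table output --------------------------------------------------

def write_bedgraph(
    path: str | os.PathLike,
    chrom: str,
    region_start: int,
    bin_size: int,
    values: np.ndarray,
    track_name: str | None = None,
) -> None:
    with open(path, "w") as fh:
        if track_name:
            fh.write(f'track type=bedGraph name="{track_name}"\n')
        for i, v in enumerate(values):
            if not np.isfinite(v):
                continue
            s = region_start + i * bin_size
            fh.write(f"{chrom}\t{s}\t{s + bin_size}\t{v:.6g}\n")


def windows_to_frame(windows) -> pd.DataFrame:
    rows = []
    for w in windows:
        r1, r2, r3 = w.criterion_ranks if w.criterion_ranks else (None, None, None)
        rows.append(
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "hits": w.hits,
                "total_length": w.total_length,
                "weighted_coverage": w.weighted_coverage,
                "rank_hits": r1,
                "rank_total_length": r2,
                "rank_weighted_coverage": r3,
                "overall_score": w.overall_score,
                "overall_rank": w.overall_rank,
                "n_windows_total": w.n_windows_total,
            }
        )
    return pd.DataFrame(rows)


def write_windows_tsv(windows, path: str | os.PathLike) -> None:
    windows_to_frame(windows).to_csv(path, sep="\t", index=False)


def write_windows_bed(windows, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for w in sorted(windows, key=lambda w: (w.chrom, w.start)):
            name = f"window_rank_{w.overall_rank}"
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{name}\t{w.overall_rank}\t.\n")


def ensure_dir(path: str | os.PathLike) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
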