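# lociscape

Genome-wide ranking of lncRNA-enrichment windows, with the companion
locus-architecture analyses used to study antigen-receptor loci:
lncRNA feature classification, virtual-4C interaction calling from
Hi-C contact matrices, and ATAC-seq peak score normalization. A
synthetic-data module generates desk-scale inputs with planted
statistical structure so the whole pipeline can be run and validated
without any sequencing data.

## The problem

Antigen-receptor loci such as the immunoglobulin heavy-chain (Igh)
locus express large numbers of unannotated long non-coding RNAs
(lncRNAs) while they undergo V(D)J recombination. Finding regions of
the genome where such expression is exceptional, and relating it to
locus topology (enhancer hubs, chromatin loop anchors) and chromatin
accessibility, requires a reproducible ranking procedure and a handful
of standard 3D-genomics and ATAC post-processing steps. This package
implements those steps as a tested library with a CLI.

## The core procedure

1. **Filter** assembled transcripts: mature (exon-summed) length
   ≥ 300 nt and expression ≥ 0.3 FPKM, optionally dropping transcripts
   overlapping known annotation.
2. **Bin** the genome into 100 kb bins and accumulate three criteria
   per bin, assigning each transcript to the bin of its 5′ end:
   - *hits* — number of transcripts,
   - *total length* — summed mature length (bp),
   - *weighted coverage* — Σ length × FPKM.
3. **Merge** expressing bins into windows: bins separated by ≤ 2 empty
   bins belong to one window; a run of > 2 empty bins is a window
   boundary. Interior empty bins count toward the window span with
   zero criteria.
4. **Score and rank**: each criterion is ranked genome-wide
   (1 = largest, ties share the minimum rank); the overall window
   score is the rank sum, and windows are ordered by ascending score
   (overall rank 1 = most enriched). A `raw_sum` mode that sums the
   raw criterion values instead is available.
5. **Locate** loci of interest: report the windows overlapping a query
   interval, their ranks, and whether the locus is contained in a
   single window.

Companion analyses:

- **Contact maps** — matrix balancing (diagonal rescaling to equal row
  sums), stratum-adjusted correlation (SCC) between replicates,
  SCC-gated replicate merging, virtual-4C viewpoint profiles smoothed
  with a 30 kb rolling window at 10 kb bins, top-15 % interaction
  calls intersected across replicates, and quantile-normalized
  difference maps.
- **lncRNA features** — mono/multi-exonic classes, sense/antisense
  orientation against a reference strand, overlap and ≤ 500 bp
  proximity to gene segments, a 2×2 Fisher test of overlap × usage,
  and a Mann–Whitney comparison of expression between exonic classes.
- **ATAC peaks** — score-per-million (SPM) conversion
  (spm = score / (Σ scores / 10⁶)), greedy cross-sample consensus
  merging, a ≥ 2-samples-at-SPM ≥ 2 reproducibility filter, and
  promoter-insert count normalization (−300/+100 bp windows around
  TSSs, strand-aware).

## Worked example

Run the full synthetic pipeline (simulate → rank → features → v4c →
atac) with one command:

```bash
lociscape run --seed 7 --out run
cat run/report.md
```

```
# lociscape run report

## Locus window rank

- locus: chr1:20000000-23000000
- best overlapping window rank: 1 of 95
- single window: True

## lncRNA features

- transcripts: 186 (mono-exonic 169, multi-exonic 17)
- antisense: 104/186
- segment overlap x usage odds ratio: 1.420 (Fisher p=1)

## Virtual 4C

- replicate SCC: 0.9474
- replicate-intersected calls: 42 bins

## ATAC consensus peaks

- reproducible peaks: 91 (of 159 pre-filter)
```

The simulated genome (5 × 50 Mb chromosomes, 0.5 transcripts/Mb
background) carries a 3 Mb locus with 40× transcript density and 5×
expression: the ranking recovers it as the overall rank-1 window of 95
and, in this run, inside a single window. The feature tallies reflect
the generator's mono-exonic (90 %) and antisense (45 %) probabilities;
the odds ratio near 1 shows segment usage was planted independently of
lncRNA overlap. The two simulated Hi-C replicates are concordant
(SCC 0.95 > 0.9) and the intersected top-15 % calls cover 42 of the
297 eligible 10 kb bins around the viewpoint. Of 159 merged consensus
peaks, 91 survive the ≥ 2-sample SPM ≥ 2 filter — exactly the planted
true peaks present in ≥ 2 samples.

Each stage is also available separately (`lociscape simulate ...`,
`rank-windows`, `features`, `v4c`, `diffmap`, `atac-spm`); see
`lociscape --help`.

## Layout

```
src/lociscape/
  synthetic.py   generators: transcriptome, gene segments, contacts, peaks
  windows.py     filtering, binning, window merging, scoring, ranking
  features.py    exon/orientation classes, proximity, usage association
  contacts.py    balancing, SCC, virtual 4C, calling, difference maps
  peaks.py       SPM, consensus merge, reproducibility filter, normalization
  io.py          GTF / BED / narrowPeak / matrix-dump readers and writers
  pipeline.py    end-to-end orchestration and reporting
  cli.py         command-line interface
docs/methods.md  model assumptions, parameter choices, limitations
```
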