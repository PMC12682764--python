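# Methods

## Window ranking model

The ranking procedure treats lncRNA enrichment as a binned occupancy
problem. The genome is tiled with fixed 100 kb half-open bins
(`bin_size`, bp). Each filtered transcript is assigned to exactly one
bin — the bin containing its 5′-most genomic coordinate (start on +,
end−1 on −). Single-bin assignment makes the three criteria (hits,
total mature length, Σ length × FPKM) exactly additive: their sums over
all windows equal the sums over all transcripts, an invariant the test
suite checks. An `all_overlapping` mode assigns a transcript to every
bin its span touches, apportioning length and coverage by overlap
fraction; it is provided for sensitivity analysis but breaks the exact
conservation property by design.

Transcript length means *mature* (exon-summed) length throughout: the
≥ 300 nt filter is a property of the spliced product, not of the
genomic footprint, so a short transcript with a long intron does not
pass on span alone.

Windows are maximal runs of expressing bins in which consecutive
expressing bins are separated by at most `max_gap_bins` (default 2)
empty bins; the window span runs from the first to the last expressing
bin, so window coordinates are bin-aligned and single-bin windows are
possible. Interior empty bins belong to the window with zero criteria.

Scoring uses rank aggregation: each criterion is ranked genome-wide
with 1 = largest and ties sharing the minimum rank of their group
(competition ranking), and the overall score is the sum of the three
criterion ranks. Rank aggregation is the default because the criteria
have incommensurate units (a count, bp, and bp·FPKM); summing raw
values would be dominated entirely by weighted coverage. The
alternative reading — summing the raw criterion values — is kept as
`score_mode="raw_sum"`. Overall ranking sorts by ascending score with
deterministic tie-breaks: larger weighted coverage first, then
(chrom, start). All tie rules are fixed so that reruns are
reproducible; they are conventions, not modeling claims.

`locate_locus` reports every window overlapping a query interval, best
rank first, and a `single_window` flag that is true only when the full
query interval lies inside one window's span.

### Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `min_length` | 300 | nt (mature) | lncRNA definition threshold |
| `min_fpkm` | 0.3 | FPKM | drops assembly noise; inclusive |
| `bin_size` | 100 000 | bp | resolution of the enrichment map |
| `max_gap_bins` | 2 | bins | windows tolerate ≤ 200 kb expression gaps |
| `score_mode` | `rank_sum` | — | unit-free aggregation (see above) |
| `bin_assignment` | `five_prime` | — | exact conservation (see above) |

## Feature classification

Orientation (sense/antisense) is defined against a user-stated
reference strand, since the labels only make sense relative to a locus
coding strand; the default is "−" (the configuration of the heavy-chain
locus). Overlap between a transcript and a gene segment means ≥ 1
shared base between the *spans* under half-open coordinates; exonic
overlap is deliberately not required, because chromatin-level
interference does not respect splice structure. Proximity is the gap
between closest interval ends, inclusive at exactly the threshold
(default 500 bp); abutting half-open intervals have gap 0.

The overlap × usage association is summarized as a 2×2 table over
segments with a two-sided Fisher exact p-value and an odds ratio
(Haldane 0.5 correction when a cell is empty). The Fisher test is this
package's choice of statistic — the analysis it mirrors reported the
association qualitatively — and the output labels it as such.
Expression between mono- and multi-exonic classes is compared with a
two-sided Mann–Whitney U test: exact enumeration when both groups have
≤ 20 observations and no ties, normal approximation with tie
correction otherwise.

## Contact-map analyses

**Balancing.** Matrices are balanced by symmetric iterative
proportional scaling: multiply both sides by diag(√(target/rowsum))
until the maximum relative row-sum deviation is < 1e-8 (≤ 1000
iterations), with target = mean raw row sum so merged and unmerged
matrices stay on comparable scales. Rows with raw sum below 10 % of
the median row sum are masked to NaN first; balancing a matrix twice
changes nothing beyond tolerance. This is the standard equal-row-sum
contract of Knight–Ruiz-style normalization; the Newton-accelerated
solver is unnecessary at these matrix sizes.

**SCC.** Replicate concordance uses the stratum-adjusted correlation:
Pearson correlation per diagonal stratum d, combined as
Σ w_d r_d / Σ w_d with w_d = n_d·s1_d·s2_d (stratum size × the two
stratum SDs). Strata with zero variance or < 2 finite pairs are
skipped. This weighting follows the distance-stratified design of the
published coefficient but is stated here as this package's definition
rather than asserted identical to any particular implementation.
Replicates merge (entrywise sum of raw counts) only when SCC ≥ 0.9;
otherwise the merge refuses with the measured SCC.

**Virtual 4C.** The viewpoint bin's row of the balanced matrix is
smoothed by a centered rolling mean of window_bp/bin_size bins (3 bins
= 30 kb at 10 kb resolution), stepping one bin; edge bins average over
their available neighbors; masked bins stay missing. The viewpoint bin
± 1 bin is excluded from calling — without an exclusion zone,
self-ligation-scale signal would trivially occupy the top percentile.
Calls are the bins with smoothed value ≥ the ceil(0.15·n_eligible)-th
largest eligible value; ties at the threshold are all included, so the
call count can exceed the nominal 15 % only under ties. Multi-replicate
calls are the intersection of per-replicate call sets, each thresholded
on its own profile. The percentile is computed on smoothed values over
the supplied region; computing it on raw values would be noisier but is
not offered.

**Difference maps.** Both matrices' upper-triangle values are
quantile-normalized to the mean of their two sorted vectors (ties
mapped through average ranks), mirrored to symmetric matrices and
subtracted. This pooled-pair normalization replaces the random-ensemble
reference of the original difference-map construction — a deliberate
simplification: it preserves exactly the properties the package relies
on (zero map for rank-equivalent inputs, antisymmetry under argument
exchange, planted-signal localization) without requiring an ensemble
model, but the absolute scale of the differences is not comparable to
ensemble-normalized maps.

## ATAC peak processing

SPM conversion divides each peak's −log10(p) score by the sample's
total score over one million, so per-sample SPM sums to 10⁶ exactly.
Consensus merging is greedy: pool all samples' peaks, sort by
descending SPM (ties: descending raw score, then coordinates, then
sample id — a total order, so the result is independent of input file
order), and keep each peak iff it overlaps no already-kept peak. Every
kept peak records per-sample support as the best-SPM overlapping peak
of that sample. The reproducibility filter retains consensus peaks
with ≥ 2 supporting samples at SPM ≥ 2 (both inclusive; the threshold
is read as "SPM ≥ 2"). Overlap means ≥ 1 shared base.

Promoter-insert normalization divides each sample's peak counts by the
number of insert positions in nucleosome-depleted promoter windows —
[TSS−300, TSS+100) in the direction of transcription, mirrored on the
minus strand — and rescales by the across-sample mean total so values
keep count-like units. Overlapping promoter windows are collapsed so an
insert is counted once.

## Synthetic data: what it emulates, and what it does not

The generators plant exactly the statistical structure each stage
assumes, at desk scale:

- **Transcriptome** — background transcripts at uniform density
  (default 0.5/Mb over 5 × 50 Mb chromosomes) with log-normal mature
  lengths (median ≈ 1 kb, sd-log 0.6) and expression (median ≈ 1 FPKM,
  sd-log 1.0), plus one 3 Mb planted locus with 40× density and 5×
  expression — the signature of a top-ranked enrichment window against
  a sparse background. Counts per region are Poisson; 10 % of
  transcripts are multi-exonic (2–6 exons, span inflated 1–5× over
  mature length, so the span/mature-length distinction is exercised);
  45 % are minus-strand. The expected-count cap (10⁶) guards against
  accidental density explosions.
- **Gene segments** — 180 non-overlapping 500 bp segments on a slot
  grid inside the planted locus, 80 % flagged as used, mirroring the
  V-segment tallies of a heavy-chain locus; usage is planted
  independently of transcript positions, so the expected
  overlap × usage odds ratio is 1.
- **Contacts** — symmetric Poisson matrices with expected count
  base·(1+d)^−α (defaults: base 100, α 1, 300 × 10 kb bins), planted
  anchor pairs multiplying the expected count, and an optional
  log-normal bin-visibility bias b_i·b_j (default off). The bias draws
  from its own seed so replicates simulated with different noise seeds
  share it — this is what gives replicates correlated within-stratum
  structure, as mappability and fragment-density heterogeneity do in
  real libraries. With the bias off, expected counts are constant
  within each diagonal stratum and the SCC of two independent
  replicates is near zero by construction: distance decay alone
  carries no replicate-specific signal for a stratum-adjusted
  statistic to detect.
- **Peaks** — true peaks on a slot grid shared across samples (each
  present per sample with probability 1 − dropout, default 0.2), plus
  sample-specific noise peaks; all generated intervals are pairwise
  non-overlapping so the reproducibility filter's ground truth is
  unambiguous. Scores are gamma(2, 10) draws of −log10(p).

What passing tests on these data do **not** show: robustness to
overlapping/nested transcripts, expression-dependent assembly artifacts,
unbalanced chromosome coverage, translocations or copy-number structure
in contact maps, peak-width heterogeneity, or any alignment- and
assembly-level error mode — those live upstream of this package's
inputs.

Planted v4c anchors sit 15–40 bins (150–400 kb) from the viewpoint,
the genomic scale of adjacent enhancer-hub elements at 10 kb
resolution. This range also keeps recovery decidable: under (1+d)^−1
decay, 3-bin smoothing dilutes an 8× anchor to ≈ 3.3× its local
background, so an anchor beyond ~65 bins cannot enter the top-15 %
calls even without noise, and requiring ≥ 2 Poisson SDs of margin over
the calling threshold gives d ≲ 40. The difference-map test plants its
loop 8 bins (80 kb) off-diagonal for the analogous reason: the
quantile-normalized difference at a planted pair scales like
fold·base/(1+d) and must exceed the extreme noise difference among the
~10³ near-diagonal entries.

## Problem sizes

Validation uses 5 × 50 Mb genomes (50 seeds), 300-bin contact matrices
(20 seeds), and 3-sample/100-true-peak sets (20 seeds) — sizes at which
every planted property is measurable in seconds while the Poisson and
binomial expectations still have tight standard errors.

## Known limitations

- Two recovery properties of the planted-locus design are
  intrinsically noisy at the default desk-scale density and the
  measured rates should be read accordingly: with ~2 planted
  transcripts per 100 kb bin, a locus edge bin is empty with
  probability e^−2 ≈ 0.14, so the nominal 3 Mb interval is fully
  contained in a single window in only ~70–80 % of runs
  (`planted_locus_single_window_rate`); and in the unenriched genome
  nearly every window holds one transcript, making the former locus's
  windows exchangeable with all others, so its best window escapes the
  top decile in only ~85–90 % of runs
  (`null_locus_outside_top_decile_rate`). Both are properties of the
  sparse study conditions, not of the implementation; raising the
  background density or locus multiplier tightens both.
- The window ranking assigns no significance to ranks; top-5 %/10 %
  cutoffs are descriptive.
- SCC weighting is as defined above; numerical agreement with other
  SCC implementations is not guaranteed, though scale invariance,
  boundedness and the identity case are.
- Difference maps are comparative only (see above).
- The pipeline's liftover-free coordinate handling assumes all inputs
  share one assembly.
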