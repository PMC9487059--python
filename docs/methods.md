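# Methods

This note documents the statistical model and procedural choices
behind each stage of the toolkit, what the synthetic methylome does
and does not emulate, and the numerical conventions that make runs
reproducible.

## Coordinates and formats

All internal coordinates are 0-based half-open. 1-based coordinates
exist only at file boundaries: the Bismark-style CX cytosine report
(7-column TSV: chrom, position, strand, methylated count, unmethylated
count, context CG/CHG/CHH, trinucleotide) and the BS-Seeker2 CGmap
(8-column TSV; strand inferred from the nucleotide column, unmethylated
= total − methylated). BED and bedGraph outputs are natively 0-based.
Gzip compression is detected from the file's magic bytes, never from
its extension. The context string "CG" in files corresponds to "CpG"
in memory and in all reports.

Zero-coverage cytosines are retained on ingest and excluded at
analysis time, so the coverage filter is applied once, in one place
(`AnalysisParams.min_coverage`), rather than silently at parse time.
CGmap records carry no trinucleotide; conversion emits a
context-consistent placeholder containing N ("CGN"/"CNG"/"CNN") so the
context/trinucleotide consistency rule (which exempts N) still holds.

Annotation is read from genePred or BED12; both dialects yield
identical transcript models for equivalent records. Chromosomes
present in the annotation but absent from the chrom.sizes file are a
hard error: silently dropping part of the genome is the classic WGBS
analysis bug.

## Methylation tracks and profiles

The methylation level at a site is β = n_meth / (n_meth + n_unmeth),
undefined (missing) at zero coverage; missing sites never enter any
mean. Replicates are pooled by summing counts per (chrom, pos,
strand); the context must agree across replicates at each position.

Destranding pools the two cytosines of a symmetric CpG (p on '+', p+1
on '−') into one unit anchored at p. Unpaired CpGs pass through, so
destranding is idempotent and conserves call counts exactly.

Per-context summaries use 10 fixed histogram bins of width 0.10,
left-closed right-open with the final bin closed at 1.0, so fully
methylated sites count in [0.9, 1.0]. Genome bins are 100 kb, tiled
from 0 with a truncated final bin; a bin's value is the unweighted
mean over its covered sites, and the coverage-weighted mean of bin
values therefore reproduces the genome-wide mean to float precision.

The five genomic context classes are derived from the transcript
models. A "gene" is the union span of all transcripts sharing a
gene_id (its promoter anchors at the 5′-most TSS); merged exons are
the per-gene union of all transcripts' exons; introns are the gene
span minus merged exons; the promoter is the 1 kb strand-aware
upstream window clamped to the chromosome; intergenic is the genome
minus all transcript spans. Classes are non-exclusive — a promoter
site inside a neighboring gene counts in both — with one exception:
the per-class mean report excludes promoter positions from the
intergenic class, so "intergenic" in the report carries no gene-linked
signal even though the interval set itself is the plain transcript
complement.

TSS metaprofiles use a 500 bp window sliding in 100 bp steps across
±1500 bp of the TSS: ⌊(2·1500 − 500)/100⌋ + 1 = 26 windows. Windows
are strand-oriented (window 1 is the most upstream window of the gene
regardless of genomic direction); windows extending past a chromosome
edge, or containing no covered site, are missing for that gene and are
skipped in the across-gene mean. The profile context is CpG by
default (configurable): CpG is the dominant and biologically standard
context for promoter methylation profiles.

## Hypomethylated-region segmentation

Segmentation runs on the destranded CpG track, using units with
coverage ≥ `min_coverage` (default 5, the same filter as differential
testing, for consistency). Per chromosome:

1. smooth levels with a centered running mean over `seg_smooth_k` = 3
   consecutive CpGs (edges shrink the window);
2. mark CpGs with smoothed level < `lmr_max_level` = 0.50;
3. maximal marked runs with ≥ `seg_min_cpgs` = 4 CpGs become segments
   spanning first to last CpG (half-open end);
4. classify by mean *raw* level: < `umr_max_level` = 0.10 → UMR,
   otherwise LMR.

This is an explicit threshold-run segmentation, not a hidden-Markov or
FDR-calibrated segmentation: the class boundaries (0.10, 0.50) are
this toolkit's operational definitions of "almost zero" (UMR) and
"around 30%" (LMR) methylation, and all five constants are plain
parameters. Classification is by level alone; CpG density — the other
axis on which UMRs (CpG-rich islands) and LMRs (CpG-poor) differ — is
reported descriptively (`n_cpg`, segment length) but not used to
classify, because a density classifier would need a genome-calibrated
density model that the level rule does not. With 3-CpG smoothing a
planted feature's boundary can shift by at most ⌊k/2⌋ = 1 CpG;
chromosomes with fewer covered CpGs than the smoothing width are
skipped with a warning. UMRs overlapping promoters by ≥ 1 bp
(half-open adjacency is not overlap) are reported with their gene ids.

## Differential methylation

With replicates pooled into per-sample counts, the natural per-site
test of equal methylation proportions is the two-sided exact test on
the 2×2 table [[case n_meth, case n_unmeth], [control n_meth, control
n_unmeth]] under the hypergeometric null, using the minimum-likelihood
two-sided rule (the total probability of all tables with the observed
margins whose likelihood does not exceed the observed table's, with a
1e-7 relative tolerance on the likelihood comparison to absorb float
rounding). The implementation is vectorized over sites via the
log-gamma function; the test is discrete and therefore conservative —
its empirical type-I error at α = 0.05 on 30×-coverage null sites is
about 0.025.

P-values are adjusted with Benjamini–Hochberg step-up (via
statsmodels). DMCs are sites with q ≤ `q_cutoff` (default 0.5) and
|Δβ| ≥ `min_diff_pp` (default 25 percentage points); the lenient
default q-cutoff mirrors common practice of filtering primarily on
effect size at pooled-count resolution, and both are run parameters
(the CLI exposes them as the coverage/q options). The direction is
hypo when the case level is below the control level. Testing operates
on destranded CpG units by default so DMC coordinates line up with
segmentation coordinates.

DMRs are formed per chromosome and per direction (hypo and hyper never
mix). The gap-cluster rule takes maximal chains of DMCs whose
adjacent-member distance is ≤ `dmr_max_gap` = 500 bp — the threshold
is inclusive and measured between DMC base positions — and keeps
chains with ≥ `dmr_min_dmcs` = 2 members. The smooth-like rule
filters those candidates further: ≥ 3 DMCs, mean |Δβ| ≥ 10 pp, ≥ 70
destranded CpG units in the span (covered or not), and span ≥ 1 kb.
It is a region-level filter in the spirit of smoothing-based DMR
callers, not a re-implementation of local-likelihood smoothing; with
narrow planted DMRs (10 CpGs) it correctly returns nothing.

DMC summaries report per-direction counts overall and within
promoters, distances between consecutive DMCs per chromosome, and each
DMC's signed distance to the nearest TSS in gene orientation (negative
= upstream); equidistant TSSs break the tie toward the lower
coordinate, and all outputs are deterministically ordered by (chrom,
start, direction). Gene association collects genes whose promoter
contains a DMC position or overlaps a DMR by ≥ 1 bp, as a unique
sorted list suitable as enrichment-tool input.

## Synthetic methylome

The generator builds the study conditions every test runs under:

| parameter | default | rationale |
|---|---|---|
| genome | 2 chromosomes × 300 kb | large enough for ~30k destranded CpG units yet seconds to simulate |
| genes | 40, non-overlapping, 2–5 exons | exercises all five context classes |
| CpG background β | 0.80 | the bulk of mammalian CpGs are methylated (70–90%) |
| CHG/CHH β | 0.01 | near-zero non-CpG methylation, as in somatic mammalian tissue |
| promoter UMRs | prob 0.5 per promoter, β = 0.02 | promoter CpG islands are typically unmethylated |
| LMRs | 8 blocks of 15 CpG units, β = 0.30 | intermediate-level, CpG-poor distal elements |
| DMRs | 20 blocks of 10 CpG units, Δβ = 0.40 | strong, unambiguous differential signal for recovery tests |
| coverage | Poisson(30) per site | typical WGBS depth; Poisson (not fixed) so coverage filters are exercised |
| replicates | 2 per condition | exercises replicate merging |

Promoter sequence is CpG-enriched (a CpG-island mimic) so planted
promoter UMRs are CpG-dense like real islands. LMR blocks are placed
in intergenic background (CpG-poor by construction); DMR blocks may
fall in genes or non-UMR promoters — differential signal at promoters
is what the gene-association report exists for — but never on top of
other planted features, and all planted features keep > 500 bp
separation so two plants cannot merge into one called region. Hyper
DMRs lower the shared baseline to 1 − Δβ before shifting the case up,
so the case−control difference is exactly Δβ without clipping at 1;
hypo DMRs shift the case down from the background. Methylated counts
are binomial at the site's true probability, independently per site.

Every random stream derives deterministically from the master seed via
seed sequences ((seed, 0) reference, (seed, 1) landscape, (seed, 2,
condition, replicate) sampling), so any replicate is reproducible in
isolation and identical seeds give byte-identical files.

What the simulation does *not* emulate — and what passing tests
therefore do not show about real data: read-level effects (mapping
bias, incomplete bisulfite conversion, PCR duplicates), spatial
autocorrelation of methylation beyond the planted blocks, biological
replicate variance beyond binomial sampling (no overdispersion), and
realistic genome composition (repeats, chromosome-scale domains).
Recovery results on simulated data are best-case: they validate the
counting, testing, clustering and reporting logic, not performance
under real-data noise.

## Numerical conventions

- Histogram edges: left-closed, right-open, last bin closed at 1.0.
- Gap threshold: inclusive (distance ≤ 500 clusters), between DMC base
  positions.
- Nearest-TSS ties: lower coordinate wins.
- Two-sided exact test: likelihood comparison with 1e-7 relative
  tolerance; p capped at 1.
- Smoothing edges: running-mean windows shrink at chromosome ends
  rather than padding.
- All outputs sorted deterministically; logs contain no timestamps, so
  identical inputs and seed reproduce output trees byte for byte.
- Sizes used by the test-suite simulations (single 60–100 kb
  chromosomes, 5–8 genes) are the package's chosen compromise between
  statistical resolution and suite runtime; the acceptance script uses
  the full default conditions above.

## Known limitations

- The exact test ignores replicate structure once counts are pooled;
  overdispersed replicates will inflate significance relative to a
  beta-binomial or logistic model.
- Threshold-run segmentation has no FDR calibration; segment counts
  depend directly on the level thresholds.
- The smooth-like DMR rule approximates smoothing-based callers by
  filtering gap-cluster candidates; regions without ≥ 2 DMCs within
  500 bp can never reach it.
- GTF/GFF3 annotation is not parsed (convert to genePred or BED12
  externally); BAM/FASTQ handling and alignment are out of scope.
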