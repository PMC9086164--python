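# Methods

## Editing-level model

At a candidate site the editing level in one sample is
φ = n_G / (n_A + n_G), the fraction of reads supporting the edited base
after strand adjustment. Reads carrying other alleles at the site count
toward neither term. When n_A + n_G falls below `min_coverage`
(default 10 reads) the level is *missing*, not zero: a cell with three
reads cannot meaningfully pass or fail a 1% threshold, and treating it
as 0 would bias both the filter and the group tests. Missing cells are
excluded per site from every downstream computation.

### High-confidence filter

A canonical A-to-G site is retained when its level is at least
`min_level` (default 0.01) in at least `min_samples` (default 2)
samples, **or** when it matches a known-editing-site catalogue on
(chrom, pos, strand). Position-only matching is available
(`match_strand=False`) because public catalogues differ in strand
conventions. The filter is monotone by construction: tightening either
threshold can only shrink the retained set; growing the catalogue can
only grow it.

### Strand policy

A>G implies editing on '+', T>C on '−'. Where a gene annotation is
available the host gene's strand takes precedence; an A-to-G change
antisense to its host gene is rejected by default (ADAR edits the
transcribed strand) and can be kept with `allow_antisense=True`.
Unannotated positions fall back to the substitution-implied strand.
All retained sites are stored canonically as (A, G) with a strand flag,
so a site is never represented as T>C internally.

### Per-group accounting

A site is "detected in group g" when at least `detect_min_samples`
(default 1) samples of g have a defined level ≥ `min_level`. The Venn
partition (exclusive to either group, shared, or — for sites rescued
purely by the catalogue branch — neither) always sums to the retained
total; this identity is asserted at run time and in tests.

## Consequence annotation

Each site receives exactly one category from a GTF transcript model.
Within a coding transcript, containment decides UTR/CDS/intron; in the
CDS the affected codon is rebuilt with G substituted at the edited
position and translated with the standard genetic code, distinguishing
synonymous, missense and stop-lost calls. Across overlapping
transcripts the most severe call wins under the fixed order
stop_lost > missense > synonymous > 5′UTR > 3′UTR > non-coding exon >
intron > non-coding intron > intergenic, with a deterministic
(gene, transcript) tie-break. Stop-loss behaviour follows the code
table: of the adenosines editable in stop codons, TAG→TGG and TGA→TGG
lose the stop, while TAA→TGA and TAA→TAG remain stops and are reported
as synonymous. Only transcripts on the site's own strand are
considered; a site lying solely within antisense annotation is
intergenic for its strand. Splice-region categories are deliberately
not emitted; boundary-adjacent sites classify by containment.

## Sequence context

Windows of ±`flank` bp (default 6, i.e. 13-mers) are extracted strand-
adjusted, so "upstream" is always 5′ of the edited adenosine;
minus-strand windows are reverse-complemented. Sites too close to a
contig end are dropped and logged. For every cell (position p ≠ 0,
base b) a 2×2 table contrasts the observed count of b at p against the
expected split under a background composition (the reference genome's
base frequencies by default, uniform 0.25 optionally), tested with the
two-sided Fisher exact test and BH-adjusted across all 4 × 2·flank
cells. Odds ratio > 1 flags enrichment, < 1 depletion. The background
is a single genome-wide composition, not dinucleotide-corrected — a
deliberate simplification; with a ~50/50 base composition the
nearest-neighbour preference of ADAR is already unambiguous at a few
hundred sites.

## Differential editing

Per site, levels of the two groups are compared with the tie-corrected
Kruskal–Wallis test (chi-square approximation, k−1 df). Editing levels
are bounded, often skewed fractions, so a rank test is the natural
default; a Welch t-test is available (`test="t"`) for sensitivity
analysis only. Sites with fewer than `min_per_group` (default 3)
defined values in either group are skipped — the chi-square
approximation is unreliable below that — and reported with reasons.
All-identical values are a defined no-signal outcome (H = 0, p = 1),
not an error. BH-adjusted p-values are always reported; the
significance call defaults to raw p < α (α = 0.05) with `use_fdr=True`
switching to the adjusted p. Direction is the sign of
(case mean − control mean) among significant sites.

PCA of samples over a site subset drops sites missing in more than
half the samples, imputes remaining missing cells with the site mean
(inert after centering), centers per site, and takes the SVD. Signs are
fixed by making each component's largest-magnitude loading positive, so
scores are bit-reproducible. Variance shares are reported as
percentages summing to 100.

## Cis regulation

Expression is TPM: per sample, count/effective-length rescaled to sum
to 10⁶. Effective length is the summed exon length of the gene's
longest transcript. For each site with a host gene (from the
consequence annotation), the Spearman correlation between φ and the
gene's TPM is computed over samples where both are defined, with the
two-sided t-approximation for p (adequate at the 24-sample design
scale; rank correlation makes a log transform of expression
irrelevant). Degenerate inputs (zero variance, fewer than 4 complete
pairs) are skipped with reasons. The pipeline's default scope
correlates only the significant differential sites, mirroring the
intended use; `cis_scope="all"` scans every retained gene-hosted site.

## Synthetic-data generator

The generator emulates a two-group brain RNA-seq editing study at desk
scale and is the package's test bed.

* **Genome and genes.** Random uniform-composition contigs (default
  2 × 1 Mb) host non-overlapping gene models (default 300; 85% coding)
  with 2–4 exons. Coding transcripts get a forced valid ORF — ATG,
  terminal stop, length a multiple of 3, internal stops scrubbed —
  written into the sequence.
* **Sites.** Default 3000 editable adenosines sampled by region type
  (intron-dominated mix with 3′UTR second, a few percent coding,
  matching the category spectrum typical of cortical editing panels).
  The −1/+1 neighbours are rewritten so G appears with probability
  0.05 at −1 and 0.6 at +1 (vs ~0.25 background), emulating the ADAR
  nearest-neighbour motif. Start/stop codons and their flanks are
  never touched.
* **Levels and counts.** Baseline mean levels draw from
  Beta(2, 8) (mean 0.2, the low-to-moderate range typical of
  high-confidence panels). Per-sample levels draw from a Beta around
  the group mean with concentration 50; coverage is negative binomial
  (mean 50, dispersion 5); edited reads are binomial — together a
  beta-binomial, the standard overdispersed model for allele counts.
  40 differential sites shift the case-group mean by ±0.15
  (alternating sign, clamped to [0,1]) so both directions of change
  exist. Defaults use 12 + 12 samples.
* **Expression.** Gene base means are log-normal around 200 counts;
  counts are negative binomial (dispersion 10). At each of 6 cis sites
  (one per host gene), the host gene's log-mean shifts by
  ±4 × (φ − 0.2) per sample, producing editing–expression Spearman
  correlations around 0.3–0.7 at 24 samples — the magnitude range a
  cis-regulatory analysis reports as hits.
* **Catalogue.** Half the planted sites (configurable) enter the
  known-site table, plus decoy never-edited adenosines (10% of the
  table) so the catalogue branch of the filter is exercised against
  non-candidates.

Everything descends from a single seed; identical configurations give
byte-identical files. Coordinates are 1-based closed throughout.

What the generator does **not** model: read-level artifacts
(alignment error, strand bias, duplicates), sequencing error beyond
binomial sampling, batch effects, correlated editing across sites, or
realistic transcript structure (overlapping genes, alternative
isoforms). Passing recovery tests therefore demonstrates the
statistical machinery under the stated noise model, not robustness to
the full messiness of real RNA-seq.

## Problem sizes and numerical choices

The test suite and the acceptance script run the generator at the
default study scale (3000 sites, 24 samples), a 2000-site null
calibration, and a 500-site motif panel — sizes chosen so the whole
suite completes in well under a minute of statistical computation while
keeping binomial tolerances tight (3 SE at n = 2000 is ±1.5 points on
a 5% rate). Null-calibration tolerances are 3 binomial SEs around the
nominal α. Recovery rates at fixed seeds are pinned exactly as
regression values. Fisher and Kruskal–Wallis implementations are
cross-checked in tests against exhaustive hypergeometric enumeration
and hand rank formulas respectively; BH against the textbook step-up
definition on exhaustive small p-vectors.

## Known limitations

* One transcript per gene in the generator; the annotator supports
  multiple transcripts but multi-isoform severity conflicts are only
  lightly exercised.
* The per-group "detected" rule (≥1 sample ≥1%) is one reasonable
  choice among several; the Venn counts depend on it, which is why it
  is configurable and echoed in the report.
* Spearman p uses the t-approximation everywhere; at n < 10 an exact
  permutation p would be preferable.
* The consequence annotator is minimal by design: no splice-region,
  NMD, or regulatory categories, and no transcript biotype hierarchy
  beyond coding vs non-coding.
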