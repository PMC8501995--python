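# Methods

This note documents the models, conventions and numerical choices behind
`temkit`, and what the synthetic-data tests do and do not establish about
real data.

## Coordinates and the insertion-position convention

Internally everything is 0-based half-open; emitted files use their
community conventions (SAM/GFF3/VCF 1-based, BED/bedGraph 0-based
half-open).  An insertion's *position* is defined once, package-wide, as
the 1-based reference coordinate of the base immediately 3′ of the
target-site duplication (TSD).  With that convention the TSD is the
reference interval `[position − |TSD|, position)` and the junction
caller's two breakpoints bracket it exactly.

## Synthetic-data generator

The generator emulates the design of a TE-mobilization resequencing
study: a small multi-chromosome genome, nine genome-tiling chromatin
states, eight donor copies of a ~5 kb element with identical LTRs, and
diploid lines carrying planted insertions sequenced with 150 bp
paired-end reads.

* **Genome**: uniform random DNA.  Genes are placed non-overlapping with
  random gaps; each has UTRs, 2–6 coding exons and introns; lncRNA,
  pseudogene and TE annotations are interspersed to exercise the
  feature-precedence classifier.  Chromatin-state segments have
  exponential lengths (mean 2 kb, clipped to [0.3, 20] kb) and uniform
  state labels, so each of nine states covers ~1/9 of the genome.  Two
  histone tracks (H2A.Z-like, H3K27me3-like) are elevated over
  configurable state subsets.
* **Donor family**: one consensus = LTR + interior + identical LTR;
  each copy differs from the consensus at `snps_per_copy` private
  interior positions (no position shared between copies, none in the
  LTRs).  The default element length of 4,949 bp is the consensus length
  implied by 99 full-length insertions adding ~490 kb; the LTR length
  (400 bp) is a free parameter since only its terminal 20-mers matter to
  junction calling.
* **Integration model** (Ty1/Copia): at target site *q* the
  `tsd_length` bases 5′ of *q* are duplicated so they flank the
  oriented full-length element.  Default TSD length is 5 bp,
  configurable; target sites are drawn with probability proportional to
  the preference weight of the local chromatin state, keep a 2.5 kb
  margin from chromosome ends, and default to ≥ 2.5 kb mutual spacing so
  zygosity windows never contain a neighbouring junction (site-only
  studies can lower `min_insertion_spacing`).  Heterozygous insertions
  modify exactly one of the two haplotypes.
* **Reads**: each haplotype is sequenced at `depth/2`; fragments are
  normal(400, 60) bp, resampled while shorter than the read length, and
  inward-pointing.  Sequencing errors are off by default — the analysis
  thresholds, not error models, are under test.
* **Truth alignments**: reads are projected from haplotype to reference
  coordinates; bases inside an inserted element are soft-clipped, mates
  with fewer than 20 aligned bases are recorded as placed-unmapped.
  The properly-paired flag reflects the *true fragment* (inward, insert
  size within 150–700 bp), and TLEN records the true fragment length,
  even when one mate lies wholly inside the element.  This is a
  deliberate idealization: a clipping aligner would unflag such pairs,
  halving post-filter coverage in a ±200 bp band around every junction
  and making the per-base 10× homozygosity rule fail stochastically at
  30× — an artifact of aligner behaviour, not of the zygosity method
  itself.  The truth SAM documents ground truth; aligner emulation is
  out of scope.
* **Impact tracks**: stranded per-base coverage for wt/line ×
  control/heat-stress painted at two levels (expressed = 10, silent = 0
  in TPM-like units) according to each scenario's categories, plus
  spliced transcript sequences for exonisation scenarios.  The generator
  records the *exact* category set a rule-based classifier should
  recover (e.g. an intact expressed locus also satisfies
  `normal_transcript`; a heat-response gain with intact structure is
  booked as `upregulated` plus the cross-condition gain flag).

What passing these tests shows: the algorithms are correct on error-free
data at the stated depths, exactly as specified.  What they do not show:
robustness to sequencing error, mapping ambiguity in repetitive
reference regions, aligner-specific clipping/proper-pair behaviour, or
biological noise in expression tracks.  All detection thresholds are
exposed in configuration so they can be re-tuned on real data.

## Junction calling

Exact-match flank anchoring (no mismatches) is used: adequate and fully
deterministic at desk scale; mismatch tolerance is left as a
configuration hook.  Each read *and its reverse complement* are scanned,
which makes the caller invariant under reverse-complementing the input.
Flanks shorter than 20 bp are discarded; multi-hit flanks are dropped
when unique anchoring is required (default).  Head/tail breakpoints of
the same orientation on the same chromosome pair greedily: each left
(5′-genomic) anchor takes its nearest admissible right anchor within
30 bp, ties to the lower coordinate; a right anchor claimed twice flags
the resulting calls ambiguous.  Minimum support is one head and one tail
read, configurable.  The TSD is inferred from anchor geometry, not from
a fixed length.

## Zygosity

Filtering follows the cohort recipe: primary, non-duplicate, properly
paired records with |TLEN| ∈ [150, 700] and MAPQ strictly greater
than 28.  "Spanning" is defined conservatively: a read spans only if its
alignment is unclipped and strictly contains the insertion point
(start < point ≤ end, 1-based); soft-clipped junction alignments are
junction evidence, not spanning evidence.  A pair spans if both mates
are unclipped and the outer fragment interval contains the point.  The
2 kb window is centred on the point (truncated and flagged at contig
ends); coverage is per-base from filtered records only.  Verdicts:
homozygous iff min coverage ≥ 10× and zero spanning evidence;
heterozygous iff any spanning evidence with sufficient coverage;
undetermined otherwise.  The pooled rule is homozygous only when every
sibling is homozygous, undetermined only when all are.

## Copy attribution

The consensus takes the majority base per alignment column (ties broken
by alphabet order; such columns are excluded and flagged).  A column is
a copy-private SNP iff exactly one copy deviates.  LTR columns are
flagged and never used for attribution.  Allele frequency = alt reads /
total reads at the position, requiring ≥ 5 covering reads (configurable)
— the frequency-estimation floor is a package choice, as no minimum is
inherent to the method.  Control calibration (weights = expected 1/8
over observed control frequency) applies to genomic data only;
transcriptome/eccDNA-style datasets use unweighted means, since no
single-dose control exists for them.  Abundances are renormalized to sum
to one over attributable copies.

## Site preference

Feature precedence resolving overlapping annotation: coding exon > UTR >
intron > lncRNA > pseudogene > TE > intergenic; baselines are the
fractions of the genome each class covers after applying the same
precedence, so observed and baseline columns are directly comparable.
Signal profiles use 50 bp bins over ±1 kb (40 bins); bins falling off a
contig are excluded bin-wise.  Metagene positions are strand-corrected
percent of annotated feature length (gene bounds including UTRs).

Hotspots use greedy left-anchored clustering: a cluster extends while
the next insertion lies within the 10 kb window of the cluster's
leftmost member — deterministic and step-free, verified against an
exhaustive oracle.  The randomness null tiles the genome into
window-sized bins and compares the histogram of insertions-per-tile
against the Poisson expectation for n insertions over G/window tiles,
pooling tail (and, for tiny rates, head) classes to expected counts ≥ 5.
The statistic is referred to chi-square with k − 2 degrees of freedom:
one constraint for the number of tiles and one for the fixed number of
insertions.  Under a uniform-insertion null the resulting p-values are
uniform (verified by simulation); with k − 1 they are visibly
miscalibrated.

Target-gene expression uses Kruskal–Wallis across the target set and
four random same-size gene sets (sampled without replacement from the
non-target background, matched on count only), with two-sided rank-sum
pairwise post-hoc tests under Bonferroni correction — the multiple-
testing choice is a package default, as is the number of random sets.

## Mutational load

A variant is private to a line iff that line carries the ALT allele (any
non-reference genotype counts as carrying) and every other line is
homozygous reference; multi-allelic records are split per ALT before the
privacy test.  All carrier thresholds are inclusive: DP ∈ [10, 60],
GQ ≥ 40, alt AD ≥ 5, site MQ ≥ 30.  CNV privacy uses same-type events
with reciprocal overlap ≥ 50%.  The one-sample t-test is the standard
two-sided Student test; it reproduces the published cohort's SNP-vs-HS
p-value (0.0423) and both printed indel p-values, with the caveat that
the published text pairs the two indel p-values with the opposite
controls than the computation gives (vs 143 → 0.9286, vs 135 → 0.6562).
The published SNP-vs-drug-control and both CNV p-values are *not*
reproduced by this test on the printed columns; the package reports the
computed values and does not attempt to guess the variant of the test
that produced the published ones.

## Transcript impact

All numeric thresholds are package-defined and exposed in
`ImpactConfig`: expressed threshold 1.0 (mean coverage over transcribed
bases), breakpoint tolerance 100 bp, antisense threshold 1.0, fold
change 2.0, exonisation k-mer 31, minimum fusion extension 200 bp.
Rules, per condition, for an insertion inside a gene:

* silent_both / knockout from wt-vs-line expression over transcribed
  bases; antisense from the antisense-strand mean (independent of sense
  structure).
* truncation_5p/3p: the line's expressed transcribed span is missing
  more than the tolerance at the transcript's 5′/3′ end *and* the
  expressed edge lies within the tolerance of the insertion point.
* exon skipping (exon containing the insertion silent between expressed
  flanking exons) and intron retention (intron nearest the insertion
  expressed between expressed flanking exons) use absolute thresholds
  against wt.
* fusions: the contiguous expressed run continues ≥ 200 bp beyond the
  gene boundary in the line but not in wt; overlapping another annotated
  feature makes it a gene fusion, otherwise intergenic.
* exonisation: any 31-mer of the element (or its reverse complement) in
  the locus's line transcript but not its wt transcript.
* expression calls (up/down/normal) apply only to structurally intact
  loci; the wt mean is floored at a tenth of the expressed threshold so
  activation from silence registers as upregulation.
* acquired heat response (cross-condition): line expressed under heat
  stress, wt silent under heat stress, line silent under control.

Ambiguous multi-effect loci follow these explicit precedences rather
than manual curation, and may diverge from a curator's call on edge
cases by design.

## Problem sizes

The test and acceptance cohorts use a 2 × 200 kb genome with 50 planted
insertions at 30× (junction calling and zygosity), 20 random
eight-copy mixtures at 300× consensus depth (attribution), 100 cohorts
of 200 weighted sites (preference), 100 uniform replicates of 300
insertions over 2 Mb (hotspot null), 10⁴ random 5-mers (logo) and 200
impact scenarios across five replicate genomes.  These sizes make the
whole suite run in about a minute while keeping every statistical check
comfortably powered.

## Known limitations

* No sequencing-error or mapping-ambiguity model; recall/precision of
  1.0 on clean data is an upper bound, not a field estimate.
* Donor copies are not embedded in the reference genome, so ancestral-
  copy junction signal (which a real study filters out) is not
  simulated.
* The zygosity caller's coverage rule inherits the truth-SAM
  proper-pair idealization described above.
* Truncated/solo-LTR insertions and non-LTR TE families are out of
  scope; the junction model assumes full-length elements with intact
  terminal motifs.
* The hotspot chi-square follows one explicit operationalization of a
  "10 kb sliding window"; other window-stepping conventions would give
  slightly different tallies.
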