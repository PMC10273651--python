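# Methods

This note records the models implemented in `circsam`, the defaults and the
reasoning behind them, what the synthetic data generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## Coordinates and gene models

All internal coordinates are 0-based half-open; GFF3 input and circRNA
identifiers of the form `chrom:start-end` are 1-based inclusive and are
converted exactly once at the I/O boundary. Gene models keep a single mRNA
isoform per gene (the first listed in the GFF3), applied uniformly across all
stages so that the control-exon null and the catalog annotation use the same
exon universe. Exon lists are stored 5′→3′ in transcription order; on the
minus strand that is descending genomic coordinate, and all sequence
extraction returns the reverse complement for minus-strand intervals. `N`
bases are allowed in genomes and are treated as universal mismatches by every
alignment and scoring routine.

## Consensus catalog

A BSJ locus is *supported* for a (tool, condition) when it appears in at
least `min_replicates` (default 3 — i.e. all biological replicates) and at
least one replicate reports `min_reads` (default 2) back-spliced reads. The
read rule is deliberately per-replicate; a pooled variant
(sum across replicates ≥ threshold) is available as `pooled_reads` because
call tables from different detectors are sometimes aggregated upstream.
Supported loci are merged across tools and conditions by exact
(chromosome, start, end); strand is ignored at this step because detection
tools report it inconsistently, and is later inherited from the parent gene.
The tool-combination (Venn) map partitions the catalog by construction.
Cross-catalog tissue comparison uses Needleman–Wunsch global identity
(match +1, mismatch −1, gap −2; identity = matches / alignment columns) with
a same-chromosome gate and a 0.90 threshold.

## Annotation

*Exonic* means the BSJ interval overlaps at least one annotated exon — the
operational definition used for back-splice catalogs — rather than requiring
both ends to sit on splice sites; *intronic* requires containment in a single
intron; *intergenic* means no gene overlap. Exons belong to a circRNA when
they are fully inside the BSJ interval or when they are boundary exons whose
splice site coincides with a BSJ end (exact by default; a symmetric ±2 nt
slack is available for detectors with junction wobble). The position class is
`middle` when neither the first nor last exon of the parent gene is included;
single-exon genes get their own class. Mature length is the sum of the
circularized exon lengths clipped to the BSJ interval. Because published
catalogs differ in the denominator they quote, the 2–4-exon and middle-exon
shares are reported against all three candidate denominators (all, exonic,
multi-exon circRNAs).

## Control-exon null and RCM statistics

The null set is built in three steps: sample up to 10,000 genes (excluding
every circRNA parent gene) without replacement; enumerate every run of 1–6
consecutive exons in the sampled genes; draw controls so the exon-count
proportions match the catalog's, using largest-remainder rounding. Catalog
exon counts above 6 are pooled into the 6-exon stratum, since the null is
defined only up to 6 consecutive exons. A requested stratum with no available
runs is an error rather than a silent re-weighting.

Reverse-complementary matches are the best Smith–Waterman local alignment of
the upstream flanking sequence against the reverse complement of the
downstream one (computed with Biopython's pairwise aligner), under a
blastn-like scheme: match +2, mismatch −3, first gapped position −5, each
further gapped position −2. Raw scores below 16 (≈ 8 perfect pairs) are
no-hits and contribute 0 matched bases and 0 bitscore to the group
comparisons. Bitscores use the Karlin–Altschul form `(λS − ln K)/ln 2` with
λ = 0.625 and K = 0.41 held as configuration constants (the blastn defaults
for this scheme), not derived from first principles. The matched-bases
statistic counts identical aligned positions of the single best alignment.

Duplex stability of the matched segments is approximated by summing
nearest-neighbor stacking free energies (RNA Watson–Crick stack parameters at
37 °C, kcal/mol, embedded in `flanking.NN_STACK_KCAL`) over consecutive
complementary aligned pairs; mismatched or gapped positions contribute
nothing. This is a stacking-sum approximation, not a full secondary-structure
minimum free energy: absolute values are not comparable to a folding engine,
so all conclusions drawn from it are orderings and group contrasts, never
absolute energies.

Group comparisons use the Wilcoxon rank-sum (Mann–Whitney) test: exact
enumeration when the pooled sample is ≤ 12 with no ties, otherwise the normal
approximation with tie and continuity corrections. Length-stratified
comparisons bin by the mean of the two flanking intron lengths with default
edges 0/500/1000/2000/5000/∞ nt; bins with fewer than 3 observations on
either side are reported untested. The 2-kb-window comparison uses the
immediate 2000 nt up/downstream of the locus (clipped at chromosome ends),
oriented in transcription order.

## Differential expression

Counts are TMM-normalized: the reference sample is the one whose
75th-percentile count/library-size is closest to the mean across samples;
pairwise M values are trimmed 30% on M and 5% on A (zero-count rows
excluded), combined with precision weights, and the factors are rescaled to
geometric mean 1. Normalized counts are scaled to a common effective library
size.

For an ordered condition pair (earlier, later), each feature's signal is
M = log2(mean_later / mean_earlier) and D = |mean_later − mean_earlier| on
normalized means, with means floored at the pseudo-count k = 0.5 before the
log ratio. The noise cloud pools (|M|, D) from every within-condition
replicate-vs-replicate contrast across *all* conditions in the design, which
stabilizes the cloud for short time courses; q is the fraction of noise
points strictly dominated in both coordinates (ties do not count as
dominated). Features are called at q ≥ 0.8. Comparisons are fixed to
consecutive time points; calls are decomposed into per-comparison up/down
tallies, a Venn partition, the treatment-specific set (called in exactly one
comparison) and the common set (called in all).

This is the replicate-using empirical form of the noise-cloud method, not
the Bayesian variant; it is the simplest scheme consistent with a q ≥ 0.8
calling rule.

## miRNA sites and the ceRNA network

Sites are scored against the reverse complement of the miRNA: mismatch +1,
G:U wobble +0.5, each bulged position +1, all doubled at miRNA positions
2–13 (position 1 exempt), cutoff 4.0. At most one bulged position per site is
searched (window lengths of miRNA length ±1); a simultaneous bulge on both
sides would cancel to an ungapped frame with two breakpoints and is not
explored. Overlapping sites of the same miRNA collapse to the best-scoring
one, leftmost on ties. Circular transcripts are scanned with the sequence
extended by its own prefix (miRNA length + bulge − 1), so BSJ-spanning
windows are visible and flagged; rotating the circular sequence leaves the
recovered site set invariant. The ceRNA edge table contains unique
circRNA→miRNA and miRNA→mRNA edges, the latter restricted to miRNAs with at
least one circRNA site; mRNAs are scanned linearly on the supplied
transcript FASTA.

## GO enrichment

Per-term one-sided hypergeometric upper-tail p-values
(P(X ≥ k) with k = |study ∩ term|, K = |term ∩ universe|, n = |study|,
N = |universe|), with gene annotations propagated to ancestor terms first
(classic term-independent testing, no graph decorrelation), then
Benjamini–Hochberg step-up adjustment at 0.05. The universe defaults to all
genes in the annotation; terms with zero study genes are skipped.

## Synthetic data: what it emulates, and what it does not

The generator builds every gene in transcription space (exon and intron
strings), plants all sequence features there, and reverse-complements whole
genes at chromosome assembly, so planted structure is strand-agnostic.
Defaults: 4 chromosomes × 300 kb, 160 genes (1–9 exons of 90–300 nt, introns
80–600 nt), 40 single-gene circRNAs spanning 1–6 consecutive exons (mode
2–4, placed away from terminal exons so flanking introns exist), plus 2
circRNAs spanning adjacent gene pairs, 3 second-isoform circRNAs, and 2
circRNAs from single-exon genes. circRNA parent genes draw introns from a
longer range (600–2500 nt), reproducing the length asymmetry that real
catalogs show and that motivates the length-stratified RCM test. 80% of
eligible circRNAs receive a 60-nt element in the upstream flanking intron
and its (by default exact) reverse complement in the downstream one.

Call tables emulate 4 detection tools over 4 conditions × 3 replicates with
5% replicate dropout and random noise loci constructed to fail the support
rules (too few replicates, or single-read support everywhere). Counts are
negative-binomial around condition means drawn log-uniformly from 100–300,
dispersion 0.05. With 3 replicates and a fold change of 4, the q ≥ 0.8 rule
sits close to its information limit for down-shifts when expression spans
many octaves or dispersion is larger: the noise cloud's D coordinate from
highly expressed features then dominates weakly expressed signals. The
defaults therefore model a tight, well-measured abundance band; this is a
property of the absolute-difference D statistic itself, and analyses of very
heterogeneous or noisier data should expect lower sensitivity at the same q
threshold. Planted differential expression is a step change at one
consecutive condition pair (30% of circRNAs), plus two "common" circRNAs
whose means zigzag so that every consecutive pair differs by the planted
fold change without compounding across the series.

Ten 21-nt miRNAs are generated; planted binding sites are exact reverse
complements (or carry one mismatch outside the doubled core) written into
circ exons — one site split across the BSJ seam so that it is only
recoverable by circular scanning — and into non-parent gene transcripts as
mRNA targets. The first GO term is packed with circRNA parent genes to give
the enrichment stage a planted positive.

Not emulated: read-level data (FASTQ, alignment), sequencing error,
multi-isoform genes, strand-inconsistent tool output, coordinate wobble
between tools (the ±2 nt slack path is exercised only by unit fixtures), and
any sequence composition realism (GC content, repeats). Passing tests on
this generator therefore validate the pipeline's logic and statistics, not
detector behavior on real reads.

## Problem sizes and determinism

All randomness flows from single seeded NumPy generators; the same seed
yields byte-identical files, and two pipeline runs with the same config and
seed produce byte-identical outputs (the manifest hashes inputs and
parameters, not the output directory). The shipped analyses use the default
toy scale — ~1.2 Mb genome, 160 genes, ~43 circRNAs, 150 controls — which
keeps a full pipeline run under half a minute while leaving every statistic
comfortably powered for the planted effect sizes.
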