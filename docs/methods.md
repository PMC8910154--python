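# Methods

This note records the scientific and numerical choices behind each stage of
the pipeline: what is computed, under which assumptions, and where the
design was genuinely open.

## Read preprocessing and alignment

Reads are adapter-trimmed by removing the longest read *suffix* that
exactly matches a *prefix* of the configured adapter, requiring at least
5 nt of match — the standard 3′-adapter geometry of small-RNA libraries.
Size filtering keeps 20–32 nt inclusive, the piRNA length range. Quality
values are passed through untouched; no quality trimming is attempted.

The built-in aligner indexes both genome strands with k-mers of length
`min_len // 2` (10 by default). By the pigeonhole principle, any placement
of a read of length ≥ 2k with at most one substitution contains an exact
match in one of the two seed windows `[0, k)` or `[k, 2k)`, so seeded
candidate verification is exhaustive for the ≤ 1-mismatch contract — the
test suite confirms exact agreement with a position-by-position Hamming
scan. Reads with more than 50 distinct placements are discarded entirely.
Indels, splicing, and quality-aware scoring are out of scope; cohorts
aligned externally can be ingested as SAM/BAM instead, where the placement
count x is taken from the number of reported records per read name.

## Hierarchical annotation

Exclusion precedes annotation: a read is removed if **any** placement
overlaps the small-ncRNA exclusion track by ≥ 1 bp on either strand. This
is the most conservative reading of "excluding reads aligned to other small
ncRNAs" — a multi-mapper touching a tRNA locus once is wholly discarded.
piRNA assignment then requires ≥ 50 % of the read length inside a piRNA
locus, strand-agnostic, mirroring interval-overlap (featureCounts-style)
annotation against a piRBase-like locus track rather than sequence-identity
matching. Both thresholds are configuration keys. When one placement
overlaps several piRNA loci, the read is assigned to all of them and its
weight split, so total count mass is conserved.

## Quantification

`counts[p, s] = Σ 1/(x · m)` over reads assigned to locus p in sample s,
where x is the read's placement count and m the number of loci tied at that
placement. Library size defaults to the total aligned-read count *before*
ncRNA exclusion; this normalizer is stable against annotation choices and
is switchable to post-exclusion totals. Presence calling uses strict
inequalities on raw counts (thresholds are read counts, not normalized
values): expressed iff `> min_all` in **all** samples or `> min_half` in at
least ⌈n/2⌉ samples. Defaults are (2, 10); the ovary-style variant is
(2, 5). The per-chromosome RPKM denominator uses the count of piRNAs
expressed *in that dataset* (not a genome-wide locus count), which keeps
panels comparable across tissues; the mitochondrial chromosome is reported
separately.

## Genomic context

Each piRNA read placement is intersected with three independently
denominated panels: repeat classes (LINE/SINE/LTR/DNA are transposons,
everything else `other_repeat`), transcript biotypes
(lncRNA/protein-coding/pseudogene), and protein-coding gene features with
the priority 3UTR > 5UTR > CDS > exon per gene. Orientation is
feature-relative: sense when the read strand equals the annotated feature
strand; unstranded features count as sense. A placement overlapping several
classes within one panel splits its 1/x weight equally among them; a
placement may contribute to all three panels at once, because each panel
answers a different question against the same denominator (total annotated
piRNA reads). Group comparisons of per-sample ratios use the two-sided
Wilcoxon rank-sum test with significance stars at 0.05/0.01/0.001.
piRNA-aligned genes are called under a stringent standard (count > 10 in
≥ 50 % of samples, or > 2 in all) or a relaxed one (> 2 in more than 10
samples).

## Biogenesis signatures

The ping-pong amplification loop produces opposite-strand read pairs whose
5′ ends overlap by exactly 10 nt, uridine at position 1 of primary piRNAs,
and adenine at position 10 of secondary piRNAs. The overlap spectrum counts,
for every (plus-strand, minus-strand) placement pair on a chromosome, the
overlap k = 5′(minus) − 5′(plus) + 1 for k = 1…20, weighted 1/(x·x′). It is
accumulated via weighted 5′-position maps, which is algebraically identical
to all-pairs enumeration (verified against it in tests). The score is
z = (S₁₀ − mean S_{k≠10}) / sd(S_{k≠10}) with sample standard deviation
(ddof = 1), using the 19 non-10 overlaps as a local empirical null — the
idea behind pingpongpro's local background, without its HMM/FDR machinery.
Signal is declared at z ≥ 1.645 (one-sided 5 %, configurable). When reads
lie on one strand only, the spectrum is empty, or the null bins are
degenerate, the sample is reported as `no_signal` rather than given an
undefined score. Position-10 identity is read on the read's own 5′→3′
sequence. 1U/10A biases are tested one-sided against the uniform 0.25 null
with exact binomial tests on unweighted read counts.

## Differential expression and enrichment

Counts are normalized to counts per million library reads before testing;
since the Wilcoxon test is rank-based, this only corrects per-sample depth.
The exact null distribution is used when the combined sample size is ≤ 20
and the data are tie-free; otherwise the normal approximation with tie and
continuity corrections. Significance follows raw p < α (default 0.05);
Benjamini–Hochberg q-values are reported alongside but deliberately do not
drive the flag, keeping the decision rule of the original analysis visible
next to the corrected values. Staged designs use Kruskal–Wallis across ≥ 3
groups plus a pooled reference-vs-rest contrast; piRNAs significant in the
multi-group test but not the pooled one are flagged as stage-dependent.
Wilcoxon is the sole differential engine; negative-binomial GLM approaches
are intentionally out of scope. Batch labels are carried in the sample
sheet but not corrected for.

Enrichment is the hypergeometric upper tail P(X ≥ k) for a query of n genes
against each gene set (K in-universe members) in a universe of N, with BH
correction across sets and `gene_ratio = k/K`. The universe defaults to all
genes of the transcript track and is overridable — web enrichment services
keep their universe implicit, so making it explicit is the reproducible
substitute.

## Sparse PLS-DA

The classifier is PLS2 regression of the centered class-indicator matrix Y
on column-standardized features X. Per component, the dominant singular
pair of the deflated cross-product M = Xᵀ Y is found by power iteration;
sparsity is imposed inside the iteration by soft-thresholding the x-weight
vector at the (keepX+1)-th largest magnitude — keeping exactly keepX
non-zeros — followed by renormalization; X and Y are then deflated on the
component scores. Component-1 loadings of a dense fit equal the leading
left singular vector of XᵀY (tested against SVD), and loadings agree with
the mixOmics reference implementation to machine precision on dense and
sparse toys. Signs follow the convention that each loading's
largest-magnitude entry is positive.

Prediction uses the regression coefficients B = W(PᵀW)⁻¹Cᵀ and assigns the
class with the largest predicted indicator value ("max.dist"); centroid and
Mahalanobis distances are not implemented. Model selection is two-stage, in
protocol order: the component count H is chosen first by leave-one-out
accuracy over 1–10 dense fits (ties → fewer components), then keepX is
grid-searched per component sequentially with earlier choices fixed and
later components dense (ties → smaller keepX). The default grid is
{5, 10, 25, 50, 100, p} intersected with the feature count. LOO folds whose
training split loses a class are skipped with a warning and the divisor
adjusted. Two-class AUC uses the positive-class continuous score;
multi-class uses macro one-vs-rest averaging. VIP scores are
`VIP_j = sqrt(p · Σ_h SS_h (w_{jh}/‖w_h‖)² / Σ_h SS_h)` with SS_h the Y
variance explained by component h; mean VIP² = 1 holds by construction. The
whole procedure is deterministic — the seed parameter exists for interface
stability only.

## Synthetic data

The generator plants every structure the analysis is meant to detect, at
study-like conditions: two- or three-group cohorts (default 14 vs 14,
matching a brain case/control arm), log-normal locus baselines with
group-wise fold changes (default six 4-fold loci), log-normal per-sample
depth factors with unit mean, Poisson-realized counts, decoy
tRNA/rRNA/miRNA/snoRNA loci (15 % of reads), piRNA loci hosted in
transposons (20 %), 3′UTRs (15 %), pseudogenes (15 %) and lncRNAs (10 %),
~25 % of genes carrying a diverged transposon fragment in the 3′UTR, and
10 % of piRNA loci duplicated verbatim elsewhere so their reads map twice.
Germline-like presets use 24–32 nt reads, a 0.75/0.5 1U/10A bias, and emit
ping-pong mates for 30 % of reads: the mate sits on the opposite strand
with its 5′ end exactly 9 bp downstream (plus-strand coordinates) of the
primary's 5′ end, and the primary 5′ base is uridine, which makes the
mate's position 10 adenine by complementarity. Somatic-like presets use
20–30 nt reads, uniform base composition, and no pairs.

Reads are exact genome substrings; base biases are planted by choosing 5′
positions whose genomic base already satisfies them, with the forcing
probability set so the *final* fraction (including the ~¼ background rate)
matches the configured value. The one-mismatch tolerance of the aligner is
exercised by a separate option that gives a configurable read fraction
exactly one substitution. Background (unannotated) reads — 5 % of the
library — are drawn only from regions clear of every planted interval, so
each read's truth label is unambiguous; planted loci keep a 100 bp mutual
gap, far above the 20-nt ping-pong window, mirroring the sparse genomic
layout of real piRNA clusters. Per-sample depth defaults to ~3000 reads on
a 2 × 60 kb genome with 60 piRNA loci: large enough for every planted
effect to be measurable, small enough that the full cohort pipeline runs in
seconds. What the generator does **not** emulate: sequencing errors and
quality structure, PCR duplicates, repeat subfamily hierarchy, pseudogenes
sharing sequence with their parent genes, and compositional library biases
beyond total depth. Passing tests therefore demonstrate the correctness of
the algorithms under the stated generative model, not robustness to
real-library artifacts.

One consequence of library-size normalization is visible in the synthetic
cohorts and is a real phenomenon, not a bug: strongly upregulated loci
depress the counts-per-million of every other locus in a small panel, so a
two-group comparison flags null loci as compositionally shifted. The
type-I-error calibration therefore uses cohorts with no planted fold
changes.

## Pipeline and reproducibility

The workflow runs seven stages — simulate, annotate, quantify, context,
signatures, de, classify — with plain-text intermediates (FASTA, BED, GTF,
FASTQ, TSV) and a manifest of outputs with SHA-256 checksums. Every TSV
carries a `#` prologue with the package version and a hash of the full
configuration, so runs differing only in seed are distinguishable from
their outputs. Wall-clock times go to a separate log file, keeping the
manifest and all data outputs byte-identical across reruns of the same
configuration. Any stage can be re-run from the intermediates of earlier
ones. Unknown configuration keys are rejected rather than ignored.
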