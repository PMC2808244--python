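# Methods

## Coordinate and symbol conventions

All intervals are 0-based half-open (BED convention) internally; GFF3's
1-based closed coordinates are converted on read. Gene symbols are
uppercased on read so rosters from different files compare
case-insensitively. Multi-transcript genes are collapsed to one model per
symbol: the union span, the merged union of coding intervals, and a 3′UTR
defined by the 3′-most coding end — reads are attributed to gene symbols,
not transcripts, so a single per-symbol model is sufficient and avoids
double counting.

Aligned tags are consumed as a documented 6+2 column BED (mismatch count in
the score column, optional sample and uniqueness columns) rather than a
proprietary aligner format; only the first 25 bp seed of a record defines
the mapped interval.

## Tag attribution

A filtered tag (unique, ≤1 mismatch; both checks inclusive at the boundary)
is eligible for a gene when it overlaps the gene span extended by `flank`
(default 1000 bp) on **both** sides and maps on the gene's strand. The
flank is two-sided because 3′-flank reads are the motivating case but the
attribution window is defined relative to the whole annotation; a
3′-only mode can be obtained by building the index with `flank=0` and
custom models. Within a gene the category follows the fixed precedence
3′UTR > coding exon > intron > 1 kb flank, any base-pair overlap counting.
Intronic correct-orientation tags are counted toward the gene by default;
`--exclude-introns` reproduces the stricter exon/UTR-only reading.

A tag eligible for two or more genes is assigned to the gene whose 3′ end
(the poly-A-proximal span boundary) is nearest, since 3′-tag reads cluster
there; an exact distance tie is left ambiguous and unassigned. This rule is
deterministic and independent of input ordering. A tag inside a gene on the
wrong strand is `WRONG_ORIENTATION`; a tag with no gene within the flank is
`INTERGENIC`. Per sample, assigned + unassigned tags equal the filtered
input exactly (checked in tests), and shrinking the flank can only decrease
counts.

## Preprocessing

Tag-count matrices are filtered to genes with ≥25 total reads (inclusive),
then transformed. Whether the original analyses log-transformed the scaled
counts is not documented, so the transform is a knob: the default is
log2(count+1), chosen because standardized raw counts would be dominated by
a handful of very deep genes; `raw` mode is available. Samples are then
centered and scaled to mean 0, SD 1 (sample SD, n−1), computed over
observed values only. Standardization is idempotent; a constant sample is a
hard error naming the sample. Microarray log-ratio matrices follow the
companion path: probe-to-gene averaging (missing probes ignored), a ≥70%
valid-data filter (inclusive), then the same standardization. Tag-count
matrices carry no missing values — zeros are data; only the microarray path
has a missingness mask.

## Differential expression

The per-gene statistic is the SAM-style modified t (see README for the
formula) with the pooled standard deviation and a fixed fudge constant
s0 = 0.05 — fixed, not percentile-tuned, matching the source convention.
Negative d ⇒ higher in DTF, positive ⇒ higher in SFT; swapping labels
negates d bit-exactly (both group sums are computed directly, not via the
grand total, precisely so that this holds).

The FDR at each gene's symmetric cutoff c = |d_i| is the permutation
average of #{|d*| ≥ c} divided by #{|d| ≥ c}, capped at 1, with ≥
comparisons (ties included) as printed. When the number of distinct label
assignments C(n, n₁) is ≤ 20 000, every distinct assignment — including the
observed one — is enumerated exactly once; this is strictly better than
drawing 150 random assignments (which exceeds the number of distinct
assignments at these sample sizes) and is fully reproducible. Otherwise B
(default 150) assignments are drawn uniformly, and a seed is mandatory.
Each permuted statistic is computed through the identical code path used
for the observed d, so assignments equal or complementary to the observed
labeling reproduce |d| bit-exactly and are counted in the numerator the way
the formula intends. The FDR-vs-cutoff curve is reported raw (no
monotonization); a cumulative-minimum smoothing could be layered on but is
deliberately not the default.

Gene lists use strict inequality (fdr < cut). Top-k directional lists are
restricted to genes whose sign favors the direction before ranking by |d|,
which keeps the two directions disjoint by construction; the fallback mode
takes all genes in the direction with fdr < 0.05.

## Concordance

Spearman's rho uses average ranks for ties (tag counts tie frequently).
The paired Wilcoxon signed-rank test drops zero differences, uses average
ranks on |differences|, and for n ≤ 25 computes the exact null of W⁺ by
convolving the per-rank two-point distributions on a half-integer lattice —
mathematically identical to enumerating all 2ⁿ sign vectors, which the
tests verify literally for n ≤ 12. Beyond n = 25 a normal approximation
with continuity correction is used. Both one-sided (greater) and two-sided
(twice the smaller tail, capped at 1) p-values are reported, because the
sidedness of the published platform comparison is not stated: seven
uniformly positive differences give one-sided 1/128 ≈ 0.0078 and two-sided
1/64 ≈ 0.0156. The scatter of t-statistic vectors is summarized by Pearson
correlation and by the first principal-component line — the leading
eigenvector of the 2×2 covariance matrix through the centroid (total least
squares), which treats the two axes symmetrically.

## Exclusivity

Fractions are pooled per group over the filtered roster ("fraction of the
group's reads in the full data set"), not averaged per sample. The ratio is
DTF fraction over SFT fraction, infinite when only DTF expresses the gene
(serialized as `Inf`); swapping labels maps ratio to 1/ratio exactly. The
reported lists require, on both preparations, strict exclusivity or a
≥100-fold ratio plus ≥100 reads; the read threshold counts both groups by
default, with a `favored` scope restricting it to the favored group (both
readings of the published threshold are defensible).

## Enrichment

The EASE score decrements the overlap count by one (floored at zero) before
taking the one-sided hypergeometric enrichment tail, computed through the
log survival function for stability; it is always ≥ the plain Fisher p.
The background is the analyzed gene roster (e.g. the cross-platform common
set), standard over-representation practice — not the whole genome. Set
members outside the background are dropped (logged) before counting.
Reported sets need ≥10 query hits and EASE < 0.05; no multiple-testing
correction is applied across sets, matching how such screens are usually
reported.

## Synthetic data

The generator's defaults are the study conditions used throughout the
tests: 2 000 genes, 6 vs 6 samples, 10% of genes differentially expressed
at 4-fold (split evenly by direction), negative-binomial counts with
dispersion 0.15 scaled to a 100 000-read library. The toy genome places
non-overlapping genes on alternating strands (3 coding exons of 400 bp,
introns of 750 bp, a 300 bp 3′UTR; 1 200 bp gaps — larger than flank +
read length, so attribution in the clean limit is provably unambiguous).

Tag placement encodes the one-read-per-molecule property: each transcript
count yields exactly one 25 bp tag on the gene's strand. The distance from
the poly-A site to the tag's 3′ edge is uniform over a preparation-specific
window — 100–200 b for frozen tissue (heat-fragmented intact mRNA) and
0–80 b for FFPET (already-degraded fragments sequenced without further
fragmentation). A preparation-specific fraction of tags (frozen 0.65,
FFPET 0.50) is instead positioned uniformly within the gene body, modeling
internal oligo-dT priming at A-rich stretches and annotation mismatch —
the processes that put real 3′-tag reads into coding exons and introns.
These two fractions were fixed analytically so that the simulated share of
annotated reads falling in the 3′UTR is ≈41% (frozen) and ≈50% (FFPET),
the regimes the protocol exhibits on real tissue. Contamination —
poly-A-only reads (default 20% of all reads, emitted as non-unique records
since the pipeline consumes alignments), non-unique mappers (5%), and
2-mismatch reads (2%) — is expressed as fractions of the total emitted
read stream.

What the simulator does **not** model: transcript isoforms and alternative
polyadenylation, sequence-level errors and quality scores, mappability
structure, GC or amplification biases, and cross-gene correlation.
Passing tests therefore demonstrate correctness of the computational
machinery under a faithful but idealized generative model, not performance
on real libraries.

## Numerical choices and problem sizes

* Exhaustive permutation enumeration is used whenever C(n, n₁) ≤ 20 000;
  the 6 vs 6 default gives 924 assignments.
* The end-to-end recovery check runs ten simulated studies at the default
  conditions (a few seconds total); count-level simulation is used there
  because tag placement is irrelevant to the statistic, while tag-level
  runs back the quantifier checks at 25–200 genes.
* The exact Wilcoxon lattice is scaled by 2 to keep average (half-integer)
  ranks integral; tail probabilities are exact rationals represented in
  floating point.
* Standardization tolerances are 1e-9; FDR/oracle equalities are asserted
  at 1e-12.

## Known limitations

* The quantifier resolves multi-gene ambiguity by nearest 3′ end; for
  overlapping real annotations (absent from the toy genome) other policies
  (fractional assignment, discarding) are common and not implemented.
* The microarray path starts from gene-level or probe-level log ratios;
  spot flagging and within-array normalization are upstream of this
  package.
* Only two-class unpaired designs are supported by the test statistic; no
  covariates, no paired or multi-class extensions, and no q-value/local FDR
  machinery.
* The exact Wilcoxon enumeration treats ties via average ranks; mid-p
  variants are not offered.
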