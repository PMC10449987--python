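# Methods

This note records the models, estimators, numerical conventions and design
choices behind `cnvpop`, and what the synthetic cohort does and does not
emulate.

## Coordinates, genotypes, copy number

All internal coordinates are 0-based half-open; VCF input/output converts
to 1-based inclusive positions with an `END` INFO key. Genotypes are
dosage codes — the count of non-reference alleles in a diploid individual
(0, 1, 2), NaN for missing. Copy number is an affine map of dosage
(2 − dosage for deletions, 2 + dosage for duplications); every variance-
based statistic is affine-invariant, so dosage is used directly.

## Consensus merging

Calls of one SV type on one chromosome are clustered greedily: after a
canonical sort by (start, end, caller rank), each call joins the first
cluster whose *representative* interval it reciprocally overlaps at the
threshold (default 0.5 on **both** fractions), else seeds a new cluster.
Anchoring the match on the representative rather than on any member
prevents transitive chaining of marginally overlapping calls; transitivity
is genuinely underdetermined by a pairwise overlap rule, and the
representative-anchored greedy pass is this package's resolution. At the
per-sample level the representative is the best-ranked member's interval
and clusters resolve to the best-ranked caller's coordinates and (possibly
a different caller's) genotype, via separate coordinate and genotype
orderings. At the cross-sample level the representative is the running
low-median of member starts and ends — robust to a single sample's jitter.
Caller-unique calls are retained by default (`min_callers=1`); the
threshold is exposed. Samples without a member call get reference dosage 0.

Properties verified in the test suite: every input call lands in exactly
one cluster; the resolved set is invariant to input order; merging a
cohort's consensus with itself is an exact fixed point; on unambiguous
fixtures (all pairwise overlaps clearly above or below threshold) the
greedy clustering equals the connected components of the match graph; with
breakpoint jitter ≤ 1% of variant length, ≥ 99% of planted variants return
as single consensus variants.

## Filter ladder

Stage order: genotype-quality masking → SNP-evidence false-positive
detection → Hardy–Weinberg filter → (analysis-specific) MAF filter. A
`FilterReport` enforces input = removed + retained at every stage.

**HWE.** Pearson χ² with df 1 and no continuity correction, allele
frequency estimated from the genotype counts; monomorphic variants are
untestable (p = 1). The test runs per (variant, population); within each
population the Bonferroni threshold is α divided by the number of
polymorphic variants tested *in that population*, and a variant is removed
when significant in any population. Limitation: the asymptotic χ² tail is
anti-conservative when an expected genotype-class count falls to ~1
(e.g. AF near 0.05 at 25 samples/population), so far-tail guarantees only
hold in the usual validity regime (expected counts of a few or more); the
null-calibration tests run there, and real-data users should combine the
filter with the MAF pre-filter, as the pipeline does.

**SNP-evidence check.** Only heterozygous CNV genotypes are testable. Each
heterozygous SNP inside the variant contributes its alt-allele read
balance b = alt/(ref+alt); the CNV-consistent values are {0, 1} on a
one-copy region (het deletion) and {1/3, 2/3} on a three-copy region (het
duplication), while b ≈ 0.5 indicates a normal two-copy region. A SNP
votes "supporting" when b lies within ±0.15 of a consistent value, else
"discarding"; the genotype is flagged false positive when discarding votes
outnumber supporting votes over at least 2 SNPs (both tunable). This is a
deliberate majority-vote simplification of read-level false-positive
detectors; it recovers ≥ 95% of planted balanced-het errors at ≤ 5% cost
to true hets on the standard synthetic cohort.

**MAF.** Strict inequality: MAF < 0.01 removes; 0.01 exactly is retained.

## Population statistics

**Frequency classes.** common iff AF > 0.05; low iff 0.01 ≤ AF ≤ 0.05;
rare iff AF < 0.01 — a partition. Table-style per-population class counts
use each population's own AF (a variant absent from a population is not
counted there); the sharing cross-tab uses the cohort AF by default, with
a per-population mode available, since published per-population tables
imply per-population frequencies while cohort-wide classes are the natural
choice for the sharing breakdown.

**F_ST.** Weir–Cockerham (1984) variance components a (among populations),
b (among individuals within populations), c (within individuals) per
locus, from sample sizes, allele frequencies and observed heterozygote
frequencies; the genome-wide estimate is the ratio of sums
θ = Σa / Σ(a+b+c), monomorphic loci contributing nothing. Bootstrap
p-values resample loci with replacement; p is the fraction of bootstrap θ
≤ 0, floored at 1/(n_boot + 1) (default n_boot = 10,000). Note the
estimator's known finite-sample behaviour: two *identical* samples give
θ ≈ −1/(2n−2), not 0; absence of differentiation means independent
sampling from one population, and the tests treat it that way. Parameter
recovery on Balding–Nichols cohorts (2 × 50 samples, 2,000 loci) is within
±0.01 for F ∈ {0.01, 0.05, 0.1}.

**V_ST.** Per variant and population pair:
V_ST = (V_T − V_S)/V_T, where V_T is the pooled copy-number variance and
V_S the sample-size-weighted mean of the within-population variances. All
variances use denominator n (population variance), so identical groups
give exactly 0 and the within/between decomposition is exact; V_T = 0
leaves V_ST undefined, and undefined values are excluded from averages.
For biallelic variants — two observed copy-number states, e.g. het
carriers vs non-carriers — V_ST is algebraically identical to the
heterozygosity-based fixation index (H_T − H_S)/H_T on carrier
frequencies, which the tests verify to 1e−9; with three dosage states the
two quantities differ (V_ST ≈ twice G_ST at small divergence), so the
equivalence is claimed and tested only for the binary case. The top
quintile per pair takes values at or above the 80th percentile (linear
interpolation; boundary ties included) and requires ≥ 5 defined values.

**Contingency χ².** Pearson statistic, expected = row·col/total,
df = (r−1)(c−1), no continuity correction; zero margins are input errors.
Recomputing the published 4×3 frequency-class table gives χ² = 83.66
(printed as 83.6) with p = 6.25e−16 reproduced exactly; the 2×3
location table gives χ² = 77.29 → 77.3 as printed.

**Group comparisons.** One-way ANOVA and Kruskal–Wallis on per-genome
burdens are invoked from scipy and reported as the standard tests they
are.

## Genomic annotation

Intergenic iff no gene span is overlapped. With one gene, any ≥ 1 bp exon
overlap makes the variant exonic, else intronic (exon dominance, no
fraction threshold — "intersects" semantics). More than one gene gives the
multigene category with per-gene exon/intron sub-calls; for 2×3 tallies
multigene folds by exon dominance, and the unfolded 4-way table is also
available. Strand is ignored; gene spans are transcript-union spans.
LOEUF bins 0–9: bin ≤ 4 is LoF-intolerant; bin > 4 *or unscored* is
tolerant. Intron sets per class are the union of (span − exons) over the
class's genes, merged and sorted, and never overlap the class's exons.

## Region permutation

The statistic is the number of query regions with ≥ 1 bp overlap against
the merged target set (each query counted once). Randomization relocates
each region independently: chromosome drawn with probability proportional
to its number of valid start positions (length − region length + 1), start
uniform among them; lengths are preserved and randomized regions may
overlap. The empirical p uses the add-one convention
(#{perm ≥ obs} + 1)/(n_perm + 1) — never exactly zero, floored at
1/(n_perm + 1) (2.0e−4 at the default 5,000 permutations). Alternatives
are directional (greater/less) only. Randomization is genome-wide with no
callable-genome mask by default; an exclusion mask can be supplied. The
permutation count statistic is discrete, so the add-one p is slightly
conservative; null uniformity checks therefore use query sets wide enough
(hundreds of regions) to spread the count distribution.

## LD trait linkage

SNP QC removes samples with > 10% missing genotypes first, then SNPs with
> 10% missing calls, MAF < 0.01, or HWE p below the configured level
(default 0.001, in the usual range for SNP-panel QC). r² is the squared
Pearson correlation of dosage vectors over pairwise-complete samples
(composite LD — no phasing is attempted; a haplotype-level r² helper
exists for phased input). The linkage window is anchored on the trait SNP:
candidate CNVs have nearest-breakpoint distance ≤ 1 Mb (inclusive), and a
record is emitted iff r² > 0.8 (strict). One record per (CNV, SNP) with
the SNP's traits aggregated; proximity summaries tabulate location
categories, distance quantiles and a near subset (default ≤ 5,000 bp).

## Over-representation analysis

Hypergeometric upper tail P(X ≥ k) for k list genes among K reference
genes of a term, list size n, reference size N; term gene sets are
intersected with the reference, terms outside 5–2,000 reference genes (or
empty) are skipped, and list genes outside the reference are dropped with
a warning. FDR control is Benjamini–Hochberg step-up (the conventional
choice where a procedure is not named). Private terms are those
significant in exactly one population; category tallies require a
user-supplied term→category map, since such categorizations are curated
by hand. Under a null list drawn uniformly from the reference, the mean
significant fraction at FDR < 0.05 stays below 5%.

## Synthetic cohort

The generator's defaults define the standard study conditions: a 60 Mb
three-chromosome genome; four populations (one focal founder population
plus three reference panels: 20/15/12/20 samples, matching the relative
panel sizes of cohort studies of this design at desk scale);
Balding–Nichols divergence F = 0.05 (the magnitude of the deletion-based
pairwise differentiation such studies report); 300 truth CNVs, 90%
deletions (cohort deletion:duplication ratios are ~9:1), lognormal lengths
with a 50 bp SV floor, non-overlapping within type so biallelic dosage
coding stays well-defined; three emulated callers with rank-ordered
confidence, breakpoint jitter SDs 15/30/60 bp, false-call rates 5/8/12 per
genome, miss rates 5/10/15% and genotype-flip rates 1/3/5% — loose
magnitudes, not portraits of real tools; 200 genes with 1 + Poisson(4)
exons, uniform LOEUF bins with 10% unscored, 5% disease flags; one tagging
SNP per CNV at target r² 0.9 within ±1 Mb of the CNV midpoint, where the
SNP's alleles copy the CNV's allele pair and are independently replaced
with probability s = 1 − √r²_target (allele correlation 1 − s, hence
expected genotype r² = (1 − s)²).

Randomness: one master integer seed; each stage derives an independent
substream keyed by (stage name, seed) via `SeedSequence`, so adding a
stage never perturbs another stage's draws; fixed seed gives byte-identical
outputs. Breakpoint jitter rounds to nearest integer, ties to even
(`np.rint`).

What the generator does *not* emulate: read-level data (no FASTQ/BAM),
realistic human site-frequency spectra, linkage disequilibrium between
CNVs, overlapping or multi-allelic CNVs, sex chromosomes (diploid
autosomes only), or any specific caller's error spectrum. Passing tests
on this cohort therefore demonstrate the correctness of the estimators
and the pipeline plumbing under the stated error model — not robustness
to the full messiness of short-read SV calling.

## Problem sizes

The default test suite and the acceptance script run at desk scale:
2,000-locus F_ST recoveries, 200-variant × 20-sample merge recoveries,
500-replicate null calibrations at 200 permutations, 30–50 replicate HWE
calibrations at 1,000 variants × 4 populations. These sizes put Monte
Carlo error well inside the asserted tolerances while keeping the whole
suite in tens of seconds.
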