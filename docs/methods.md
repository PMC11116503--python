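# Methods

This note records the models, parameter choices and numerical conventions
behind `rnasm`, and what the synthetic benchmark does and does not establish
about real data.

## Problem setting

Variant callers applied to tumor RNA-seq emit candidates of which only a
minority are genuine somatic mutations present in the tumor DNA. The
remainder are germline variants, A-to-I RNA-editing events (adenosine
deamination, observed as A>G on the transcribed strand, i.e. the T>C class
after pyrimidine collapse), reverse-transcription (RT) misincorporations at
low allele fraction, and alignment artifacts concentrated at soft-clipped
read ends and splice junctions. `rnasm` consumes a candidate VCF plus
per-site read evidence and applies two decision stages — a deterministic
filter bank, then a learned classifier — followed by spectrum/signature
analytics and a validation harness.

## Coordinates and formats

All internal coordinates are 1-based inclusive (VCF convention); BED's
0-based half-open intervals are converted at the reader boundary only.
Chromosome naming is preserved verbatim; a mismatch between inputs raises
rather than aliasing. Multi-allelic VCF records are split into one candidate
per ALT allele; indels flow through ingestion and may only be removed by
filters (they are exempt from the editing-specific ones). Standard formats go
through pysam (VCF/SAM/BAM), pyfaidx (FASTA) and gffutils (GTF).

## Site evidence

`SiteEvidence` summarises one site: total depth; stranded alt/ref counts;
median base and mapping qualities per allele; mean fractional read position
of the alt base; fraction of alt reads soft-clipped within 10 bp of the site;
multimapper fraction; mean per-read mismatch count; distance to the nearest
annotated exon boundary of an overlapping gene (−1 when intergenic); median
depth over 25 bp flanks on each side (median rather than mean, robust to
splice-boundary coverage cliffs); optional second-aligner depth/alt counts
and second-caller alt count (sentinel −1 = absent, which renders the
concordance filters inert); and the duplicate-read fraction. When extracted
from alignments: soft-clipped bases never count as allele support, bases
under Phred 10 are excluded from allele counts but still add to depth,
duplicate-flagged reads contribute only to `dup_frac`, and deletions spanning
the site count toward depth only. Indel support requires the read's CIGAR to
place the exact indel at the candidate position. The same structure can be
ingested from a documented 26-column TSV (`docs/evidence_schema.md`), and the
tabular and alignment paths drive identical filter outcomes.

Flanking unevenness is `depth_total / max(1, median(flank_left,
flank_right))`; values well below 1 mark a coverage pit at the site, a
misalignment fingerprint.

## The 18 filters

Each filter is an independent predicate; a candidate passes the bank iff no
enabled filter rejects it, so outcomes are order-free. Defaults (all
config-exposed):

| filter | rejects when | default |
|---|---|---|
| germline | allele-exact match in matched normal, or population AF above ceiling | AF > 0.001 |
| min_depth | depth_total below floor | < 10 |
| low_mutated_reads | alt reads or VAF below floor | alt < 3 or VAF < 0.05 |
| base_quality | median alt base quality below floor | < 20 |
| mapping_quality | median alt MQ below floor or mean mismatches above ceiling | MQ < 30 or NM > 5 |
| strand_bias | two-sided Fisher exact on (ref_fwd, ref_rev; alt_fwd, alt_rev) | p < 0.001, only when alt ≥ 5 |
| multimap | multimapper fraction among alt reads | > 0.5 |
| read_position | mean fractional alt position near read ends | outside [0.1, 0.9] |
| soft_clip | soft-clipped fraction among alt reads | > 0.5 |
| junction | within N bp of an exon boundary *and* no second-aligner support | N = 3 |
| uneven_coverage | flanking unevenness below floor | < 0.5 |
| homopolymer | site touches a homopolymer run longer than ceiling | > 6 |
| cluster | ≥ K same-class A>G/T>C candidates within W bp (hyper-editing) | K = 3, W = 150 |
| editing | A>G/T>C SNV at (or within window of) a known editing site | window 0 (exact) |
| population_af | population AF above ceiling (inert without a resource) | > 0.001 |
| dual_aligner | alt support after realignment below floor (inert if absent) | < 2 |
| dual_caller | alt support from the pileup caller below floor (inert if absent) | < 2 |
| no_evidence | candidate has no evidence row | — |

Design choices worth stating: the Fisher exact test is used for strand bias
because alt counts are small at typical sites and a χ² approximation is
unreliable there; the strand-bias test is gated on alt ≥ 5 since smaller
tables cannot reach significance without pathological imbalance. The junction
filter treats boundary proximity as weak evidence that a second,
clipping-strategy-distinct aligner can rescue: it rejects only when
second-aligner corroboration is absent or below the floor, falling back to
distance-only when that evidence column was never produced. The mean-mismatch
ceiling lives inside the mapping-quality filter rather than as a nineteenth
filter, keeping the bank at eighteen. The editing filter ignores strand
(editing databases are position-keyed) and exempts non-T>C classes and
indels.

Published per-filter rejection percentages do not define what happens when a
candidate fails several filters, so the report carries both views: an
*independent* count (each filter applied alone to all candidates — the view
matching a per-filter percentage plot) and an *attributed* count (first
failing filter in the canonical order germline → depth → low-alt → quality →
mapping → strand-bias → multimap → read-position → soft-clip → junction →
uneven-coverage → homopolymer → cluster → editing → population-AF →
dual-aligner → dual-caller → no-evidence). Attribution satisfies exact
conservation: passes + attributed rejections = inputs.

## Features and classifier

26 features per candidate (order is part of the model contract): vaf,
alt_count, depth_total, log1p depth, median alt BQ, BQ delta (alt−ref),
median alt MQ, MQ delta, −log10 Fisher strand-bias p (capped at 30), mean
alt read position, soft-clip fraction, multimap fraction, mean mismatches,
junction distance (−1 → sentinel 10⁴, capped), flanking unevenness, GC of
the 100 bp window, homopolymer run, trinucleotide channel index (0–95),
substitution class index (0–5), T>C-class flag, distance to the nearest known
editing site (capped at 10⁴), count of same-class A>G/T>C candidates within
150 bp, caller quality, VAF delta vs the second aligner, second-caller alt
count, and log1p gene TPM. Missing optional evidence is imputed with the
stated sentinels so vectors are always finite.

Base learners: `RandomForestClassifier` (balanced class weights),
`XGBClassifier` (hist trees, single-thread for determinism), and an
`MLPClassifier` behind a `StandardScaler`. Hyperparameters are selected by
5-fold stratified cross-validated grid search on ROC-AUC over small fixed
grids (trees ∈ {100, 300}, depth ∈ {4, 8, None}; learning rate ∈ {0.05,
0.1} × depth ∈ {4, 8}; hidden layers ∈ {(32,), (64, 32)}), config-exposed.
The logistic meta-learner is fitted **only** on out-of-fold base
probabilities from the same fold layout, so no training row is scored by a
model that saw it — the test suite demonstrates that the in-fold alternative
inflates apparent AUC on pure noise while the out-of-fold route stays at
chance. Class imbalance is handled by class weights, not resampling, which
preserves seed determinism. Support-vector and plain logistic learners exist
behind the same registry but are excluded from the default stack. Labels for
training follow the DNA-backed convention: a candidate is positive iff it is
present in the tumor DNA (somatic or germline truth on the benchmark; on real
data, membership in a WXS/WGS-derived reference). The classifier is applied
to all post-filter candidates, not only editing-suspect classes — the
features let it be conservative on non-T>C candidates, and restricting its
domain would hard-code an assumption the model can learn.

ROC-AUC is the probability of correctly ranking a positive above a negative
(ties 0.5); PR-AUC is step-wise (average precision). Both come from
scikit-learn and are cross-checked in tests against an O(n²) pairwise oracle.

## Spectra and signatures

Substitution classes are pyrimidine-collapsed; the 96 channels follow COSMIC
SBS row order (class major, then 5′ base, then 3′ base, each A<C<G<T), with
purine-reference sites reverse-complemented together with their flanking
context. Exposures are fitted per sample by non-negative least squares
(`scipy.optimize.nnls`) against a fixed reference matrix whose columns sum
to 1, then rescaled to the sample's mutation count; reconstruction residual
is reported. Supervised NNLS refitting replaces de novo matrix factorisation
deliberately: it is deterministic, needs no rank selection, and is exactly
what per-mutation assignment requires. Assignment uses the posterior
likelihood `exposure_k·S[c,k] / Σ_j exposure_j·S[c,j]`; the argmax signature
is assigned only when its likelihood strictly exceeds 0.75, channels with
zero fitted intensity are unassigned with a flag. Optional backward
elimination (dropping signatures whose removal costs < 0.01 cosine
similarity) is off by default. The packaged 3-column reference matrix is
synthetic (constructed profiles in the COSMIC layout, named `synthA/B/C`),
not a copy of any catalogue.

## Validation harness

"Validated" means allele-exact membership of a predicted
(sample, chrom, pos, ref, alt) in the union of DNA reference sets; a
position-only mode exists behind a flag. Sites with fewer than `min_depth`
(default 10) reads in *any* platform are excluded from numerator and
denominator, making precision/sensitivity symmetric under swapping
predictions and reference. Per-patient medians use the lower median for even
counts. Binned validation curves (depth bins [0, 10, 30, 50, 100, ∞) and GC
deciles by default) flag bins under 5 sites; size-weighted bin fractions
recompose the overall fraction exactly. The expression gate for
significantly-mutated-gene analysis drops genes with mean TPM < 1 and emits a
(sampleID, chr, pos, ref, mut, gene) table for external dN/dS tooling; the
dN/dS model itself is out of scope.

## Synthetic benchmark

The generator works at the evidence level (per-site summaries, not reads) so
every downstream stage is exercised without an aligner; a small read-level
writer exists solely to test the alignment-path extractor against the same
truth. Study conditions, chosen once:

- Class mix: 40% somatic, 15% germline, 15% editing, 15% RT error, 7.5%
  soft-clip artifact, 7.5% junction artifact — artifact-heavy enough that
  every filter sees work, somatic-dominated as in a filtered call set.
- VAF models: somatic Beta(2,5) left-truncated at 0.05 (the caller-emission
  floor: a caller never emits sub-floor sites as candidates, so neither does
  the generator); RT error Beta(1,20) untruncated (permissive low-VAF calling
  is that artifact class); germline 0.5 or 1.0 (30% homozygous); editing
  Beta(2,2); alignment artifacts Beta(2,5).
- Coverage: negative binomial, mean 80 (size 10), scaled by a gene-level TPM
  multiplier clipped to [0.5, 2]; DNA-platform depth NB(mean 60, size 8).
- Evidence fingerprints: RT errors get low alt base quality (≈16) and zero
  second-caller support; soft-clip artifacts get ≥ 0.8 clipped fraction,
  end-biased read positions and zero second-aligner support; junction
  artifacts sit within 5 bp of an exon boundary with zero second-aligner
  support and a flanking coverage excess; editing sites have clean quality
  but T>C/A>G alleles on the transcript strand, sometimes in pairs within
  100 bp (hyper-editing), with only 60% recorded in the known-sites BED —
  the unknown 40% is the classifier's target.
- Genome: GC composition alternates 5 kb blocks at 30/50/70% GC so GC-binned
  analyses have spread; genes have 2–8 exons with 20 bp terminal UTRs. The
  default benchmark uses 4 × 250 kb chromosomes and 240 genes so that 2,000
  sites produce a realistic per-kilobase candidate density (the hyper-editing
  cluster filter is density-sensitive).

Everything is deterministic under a fixed seed, including output bytes. What
passing tests show: the decision logic is internally correct, order-free,
conservation-exact, and able to separate artifact classes whose evidence
fingerprints match their construction. What they do not show: performance on
real tumors, where fingerprints are noisier and correlated, editing databases
are incomplete in structured ways, and class proportions differ by tissue.
The benchmark's separability is by construction an upper bound — a rule
classifier using the generating thresholds reaches ~0.99 precision, and the
trained stack approaches it.

## Numerical conventions and edge cases

GC content uses a 100 bp window centred on the site (50 left, 49 right),
clipped at chromosome ends, N bases excluded from the denominator.
Homopolymer runs are measured within a ±30 bp scan. Empty FDR classes are
undefined (NaN), never 0. Zero spectra yield zero exposures. Sentinel flank
depths give unevenness 1.0 by convention. Strand-bias p-values are floored at
1e−30 before the −log10 transform. All randomness flows from explicit seeds;
XGBoost runs single-threaded so thread count cannot change results. Training
problem sizes in the tests and acceptance script (2,000-site benchmarks,
600-site workflow-determinism runs) were chosen as the smallest sizes at
which class counts per fold remain stable for 5-fold CV.

## Known limitations

No CRAM or structural variants; single-tumor-sample VCF semantics; second
aligner/caller evidence is ingested, never produced (adapter recipes are
documentation only); no read-level error model (per-cycle qualities,
fragment-length effects); no de novo signature discovery or indel/doublet
signatures; dN/dS and survival analytics are external.
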