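# Methods

This note documents the models, conventions and design choices behind
`utr3pred`, in the order data flows through the package.

## Coordinates and data model

All internal coordinates are 0-based half-open; GTF input (1-based closed)
is converted once at the parsing boundary. A single convention prevents
off-by-one drift between BED-sourced expressed regions (ERs) and
GTF-sourced exons. Regions without strand information carry an explicit
unstranded state (`"."`) rather than defaulting to `"+"`: ERs called from
unstranded RNA-seq have no strand, and every sequence-dependent feature
must decide strand handling explicitly (see below).

Coverage tracks answer per-base queries; positions absent from a track
report depth 0, but a query on a chromosome the track has never seen is an
error, so genome/track mismatches surface immediately instead of silently
producing all-zero features. Transcript support level (TSL) is parsed as an
integer or recorded as missing — never imputed to 1 — because the corpus
builder keeps only transcripts with TSL exactly 1.

## Training corpus

Positives are known 3'UTR exons; negatives are 5'UTR exons, internal coding
exons (ICEs), and exons of lncRNA, ncRNA and pseudogene biotypes (the
biotype lists are configurable; the defaults cover the standard Ensembl
names for each group). For every class: TSL-1 transcripts only, per-gene
union of the selected exonic intervals ("meta-transcript"), then a minimum
width of 40 nt. ICEs are the coding exons of transcripts with at least
three coding exons after dropping the first and last in transcription
order; on the minus strand the first coding exon is the genomically
rightmost one. Overlapping examples are *not* deduplicated across classes
(a pseudogene exon inside a lncRNA can appear under both labels): each
class is extracted independently, and fidelity to that per-class procedure
was preferred over tidiness.

"3'UTR exon" means any exonic interval annotated as three-prime UTR,
including multi-exon UTRs, merged per gene like every other class.

## The 41 features

| block | n | notes |
|---|---|---|
| poly(A) signal | 1 | binary PWM match flag |
| mono-/di-nucleotide frequency | 20 | counts / region length |
| mean conservation | 1 | unscored bases count 0 |
| transposon fraction | 1 | LINE, SINE, LTR, DNA, RC classes |
| DNA structural properties | 16 | conversion-table means |
| mean-EE, mean-PD | 2 | per tissue, averaged across tissues |

**Poly(A)-signal PWM.** The matrix is built from the 12 commonly occurring
polyadenylation-signal hexamers (AAUAAA, AUUAAA, AGUAAA, UAUAAA, AAUAUA,
AAUACA, CAUAAA, GAUAAA, ACUAAA, AAUAGA, AAUGAA, AAGAAA), with column
probabilities (count + pseudocount) / (12 + 4·pseudocount), pseudocount
0.1, and log₂-odds against a uniform 0.25 background. A window matches
when its relative score (score − min) / (max − min) reaches 0.95. This
reproduces the widely used "min.score 95%" scanner convention; the
convention names the threshold but not the arithmetic, so the relative
log-odds form is fixed here and verified against exhaustive enumeration of
all 4⁶ hexamers in the tests. With pseudocount 0, log(0) cells become a
large negative sentinel rather than −∞ so scores stay finite. Windows
containing N are skipped; sequences shorter than 6 nt report 0 with a
warning.

**Di-nucleotide denominator.** Frequencies are defined as occurrences
divided by region length for mono- and di-nucleotides alike. Dividing the
L − 1 overlapping pairs by L (not L − 1) introduces a uniform ~1/L downward
bias; it is documented and applied identically to every region, so it
cannot differentiate classes.

**Structural properties.** Each property maps every di- or tri-nucleotide
to a numeric value; the feature is the mean over all L − k + 1 windows
(N-containing windows skipped; a sequence with no scorable window reports 0
with a warning). The default profile requires exactly 16 properties. The
published conversion tables are an external resource, so the package ships
a deterministic *synthetic* profile (16 named properties, values drawn once
from a fixed stream — see `synthetic_structural_tables`) and loads real
tables from TSV when provided. The synthetic values are placeholders, not
laboratory-derived scales; they exercise the machinery without encoding
real structural biology.

**Entropy efficiency.** EE(x) = −Σ p(x_i) log p(x_i) / log n with
p(x_i) = x_i / Σ x_j. Terms with x_i = 0 contribute 0; an all-zero vector
reports EE = 0 (no coverage carries no uniformity information); the result
is log-base invariant and scale invariant.

**Percentage difference.** PD = |r₁ − r₂| / mean(r₁, r₂) × 100 with r₁, r₂
the depths at the first and last base. The boundary is a single base by
default; a configurable window (mean over w bases) is available because
"the reads at the boundaries" leaves the width open. r₁ = r₂ = 0 is defined
as PD = 0 — no signal, no asymmetry — avoiding 0/0; exactly one zero
boundary gives the maximum 200.

**Strand for unstranded regions.** Candidate ERs inherit the strand of
their associated gene, the gene whose 3' end they putatively extend. When
no strand is known, PAS scanning covers both strands (the signal must exist
on *some* strand) while composition and structural features use the plus
strand; scanning both strands for a binary flag is symmetric and verified
as such.

**Cross-tissue averaging** uses whatever tracks are supplied; the 39-tissue
setup of the motivating dataset is a data property, not a code constant.

## Classifier

`scikit-learn` random forest with 500 trees and minimum node size 1
(the R randomForest defaults the protocol fixes), class imbalance corrected
by downsampling every class to the minority size, re-drawn per run from the
run seed. Scaling/centring statistics are learned on each training fold
only and stored in the model; the original protocol preprocessed the whole
matrix before splitting, which leaks hold-out statistics into training, so
leakage-safe scaling is the default and `scale_globally=True` restores the
faithful behaviour. Folds are stratified by class (the protocol is silent;
stratification prevents empty-class folds in the six-class mode).
Cross-validation is 5-fold repeated 20 times by default; metrics are
reported both as the mean over all 100 runs and aggregated per repeat,
since the reference aggregation is ambiguous between the two. The deployed
model is the fold model with maximal validation kappa; ties break by higher
AUPRC, then lower model index. Variable importance reports permutation
mean-decrease-in-accuracy and Gini (impurity-decrease) importance. The
bias-variance experiment subsamples fractions 0.1–100 % of the corpus,
cross-validating each subsample over 20 repeats; at fraction 1.0 with
matching seeds it reproduces plain cross-validation exactly.

The deployment threshold (probability > 0.6, strict) lives in the ER
pipeline, not the classifier; CV confusion metrics use 0.5.

## ER pipeline

Candidates must be associated with a protein-coding gene — junction
evidence wins over proximity; otherwise the nearest gene with expression
> 0.1 in the ER's tissue, ties towards the smaller gene id — lie downstream
of the gene's 3' end within 10 kb, and satisfy 40 < length ≤ 2000 nt (the
2 kb cap reflects the upper quartile of known 3'UTR exon lengths; ≤ 40 nt
regions make several features unstable).

Tissue-specificity rules, applied in order per ER: (1) no ≥1 nt overlap
with any other tissue's ERs → absolute tissue-specific; (2) > 75 % of the
detecting tissues brain → highly brain-specific; (3) detected in ≥ 5
tissues with all start and end coordinates pairwise within 10 nt → shared;
(4) otherwise ambiguous. "Detected in a tissue" means ≥ 1 nt overlap with
an ER of that tissue — the only overlap notion the procedure defines — and
a tissue counts once however many of its ERs overlap. A prediction counts
as already annotated when ≥ 50 % of it overlaps the 3'UTR union of any
*single* reference annotation set; overlap split across sets does not
count.

## Poly(A) validation

Overlap is ≥ 1 base against the merged, non-overlapping cluster set,
strand-blind (ERs are unstranded). PPV = validated 3'UTR calls / all 3'UTR
calls; FOR = validated non-3'UTR calls / all non-3'UTR calls; empty
denominators report missing, never 0. The permutation test re-places each
prediction uniformly at random within the allowed intergenic space of its
own chromosome (chromosome and length preserved; excluded space = genes of
all biotypes plus the 3'/5' intergenic ERs; shuffled intervals may overlap
each other, matching the default of the standard shuffling tool), with
p = x/N where x counts permutations whose overlap exceeds the observed one,
and z = (O_obs − median(O_perm)) / SD(O_perm) (median per the printed
formula, SD with n−1). Ties count as non-exceedance. The exceedance p is
reported as primary because that is the formula as printed, with a labelled
two-sided companion (doubled smaller tail, capped at 1). A saturated null
(SD = 0) reports z as missing.

## RBP motifs and CNC

Motif collections are filtered to length ≥ 7 and confidence ≥ 1 on
whatever scale the source database uses, keeping the longest motif per RBP
(lexicographically smallest on ties). String motifs match exactly with
U→T and overlapping occurrences counted (whether the original counted
overlapping matches is unstated; overlapping is the more inclusive
convention). Matrix motifs match at the score cutoff whose exact null tail
probability under a uniform background is ≤ 10⁻⁵, computed by
dynamic-programming convolution of the per-position discretised log-odds
(granularity 0.01 bits, width ≤ 30); note a 7-mer's best word has
p = 4⁻⁷ ≈ 6×10⁻⁵, so very short matrix motifs can be unmatchable at that
cutoff, which the code reports rather than hides. Densities are matches per
100 nt; the overall binding score sums densities across RBPs. The negative
control is the Altschul–Erickson Euler-path shuffle, which preserves the
dinucleotide multiset and both terminal residues exactly. Set-vs-set
enrichment (brain-specific vs shared predictions) is a one-sided Fisher
exact test on motif presence per sequence with Benjamini–Hochberg
adjustment — a transparent substitute for the AME ranking statistic, whose
internals the protocol does not specify — at adjusted p < 10⁻⁵.

CNC (constrained non-conserved) scores are consumed as precomputed 10-nt
windows; a region's score is the mean over all overlapping windows, and
regions entirely inside a track gap are reported missing and excluded
downstream.

## Synthetic fixtures

The generators exist so every stage is testable without downloads. One
integer seed drives one named pseudo-random stream per generator, so adding
a generator never perturbs another and identical specs yield byte-identical
files. The training fixture plants the contrasts the classifier must
learn: 3'UTRs get a PAS hexamer ~20 nt from their 3' end (probability 0.95
by default), smooth coverage decaying towards the distal boundary (high EE,
PD near 200) and low conservation (0.15); ICEs get high conservation (0.9)
and spiky interior-confined coverage with zero boundaries (PD = 0);
lncRNAs are deliberately the most 3'UTR-like negatives (occasional PAS,
ramped noisy coverage, low conservation); pseudogene exons are 60 % covered
by a planted LINE. Default scale is 50 examples per class and 2 tissues
(600 regions at 100 per class for the end-to-end checks) — small enough
that the full suite and the acceptance script run in well under a minute
each, large enough for the rank-sum and CV assertions to be stable. A
`hard_mode` flag weakens all contrasts and makes half the lncRNAs
feature-identical to 3'UTRs, reproducing the real qualitative confusion
pattern (3'UTRs misclassify as lncRNAs above all other classes).

What the fixtures do *not* emulate: mapping artefacts, GC bias,
sample-to-sample coverage variation, overlapping genes, alternative
transcript structures within a gene, realistic conservation profiles, or
real structural-property scales. Passing tests therefore demonstrate that
the machinery is correct and that planted signal of the designed kind is
recovered — not that real-genome classification reaches any particular
accuracy. Genome-scale performance depends on the full human annotation,
deep multi-sample coverage and external 3'-end sequencing data, none of
which a desk-scale fixture can stand in for.

## Numerical choices

* Empirical p-values use the plain x/N estimator as printed, not (x+1)/(N+1).
* The permutation-test null-uniformity check requires a null overlap count
  with wide support; with few predictions or sparse clusters the exceedance
  p-value is atomic and cannot be uniform, which is a property of the
  statistic, not a defect.
* PWM scores discretised for the DP use 0.01-bit granularity; cutoffs are
  deterministic given the granularity.
* Downsampling, fold shuffling, forest seeds and permutation placements all
  derive from a single user seed; every reported quantity is reproducible
  bit-for-bit under that seed.
* Degenerate guards: EE of an all-zero vector is 0; PD with both boundaries
  zero is 0; AUROC with single-class truth is missing; PPV/FOR with empty
  call sets are missing; z with SD 0 is missing.

## Known limitations

* The synthetic structural-property tables are placeholders; real analyses
  must load published conversion tables.
* Gene association assumes non-overlapping genes; a candidate between two
  expressed genes is assigned to the nearer one only.
* The brain fraction in tissue-specificity counts a tissue once per ER even
  when several of its ERs overlap the query (the denominator for multiple
  overlaps in one tissue is otherwise undefined).
* Matrix-motif scanning is exact but O(L·w) per sequence in pure Python;
  the string-motif path is the performant default for large collections.
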