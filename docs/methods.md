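# Methods

`trnacharge` quantifies tRNA aminoacylation ("charging") from sequencing
libraries of a periodate-protection assay.  This note documents the model
behind each stage, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## The measurement principle

Mature tRNAs end in a universal 3'-CCA; the amino acid of a charged tRNA is
esterified to the terminal adenosine.  Treating total RNA with NaIO4
oxidizes the 3' ribose of *uncharged* tRNAs only (charged 3' ends are
protected by the amino acid), and subsequent β-elimination removes their
terminal A.  After deacylation, ligation of a barcoded adapter and
paired-end sequencing, a tRNA fragment whose 3' end reads `...CCA` came
from a charged molecule and one ending `...CC` from an uncharged molecule.
The per-isodecoder fraction charged,

    f = charged / (charged + uncharged),

is the quantity of interest; uncharged tRNA accumulation is the activating
signal of the GCN2 branch of the integrated stress response, which is the
biological context the default simulated study mirrors.

## Reference construction

The alignment reference is built from a genomic tRNA gene set
(gtRNAdb-style names, `tRNA-<Isotype>-<Anticodon>-<family>-<copy>`) by
collapsing genes with identical genomic sequence onto the first-seen name
(later names become aliases, written out so counts stay attributable) and
appending `CCA` to each unique sequence.  Deduplication operates on the
genomic sequence; appending CCA afterwards gives the identical entry set
either way.  Genes are grouped at the isotype-anticodon level
(e.g. `His-GTG`), the unit at which charging is aggregated and reported.
A genomic sequence that already ends in CCA still receives the appended
CCA (with a logged warning): the rule is applied uniformly, and the
builder requires genomic (pre-CCA) input rather than guessing.

## Read layout and demultiplexing

The assay fixes chemistry, not read geometry, so the package defines a
fixture layout: each molecule is `[5' adapter][insert][barcode 5 nt]
[3' adapter]`; R1 reads the insert from its 5' end and R2 starts at the
barcode, so the reverse complement of R2 positions 1-5 is the sample
barcode and the bases immediately after are the insert's 3' end — the
charging signal.  Demultiplexing is an exact barcode lookup by default
(`--barcode-mismatch 1` rescues Hamming-distance-1 barcodes only when
unambiguous); pairs without an identifiable barcode are discarded and
counted.

Adapter trimming removes the barcode from R2's 5' end and any 3'
read-through into the constant adapters from both mates.  Matching is
substitution-only against the first 16 adapter bases, requires a ≥10 nt
overlap, allows 1 mismatch per 10 nt, and picks the candidate position
with the fewest mismatches (leftmost on ties) — the fewest-mismatch rule
prevents over-trimming on low-complexity or periodic inserts.  Pairs in
which either mate retains fewer than 20 nt are removed as empty adapters
(exactly 20 nt is kept; the rule is strictly-less-than).  Read-throughs
shorter than the 10 nt minimum overlap survive trimming; the
classification rule below is designed so they cannot corrupt the call.

## Alignment and charging call

Each mate is aligned locally (Smith-Waterman) against every reference
entry; the references are tens of entries of ≤ ~100 nt, so exhaustive
search is exact and fast.  Scoring: match +2, mismatch −6, a gap of
length k costs 5 + 3k.  A mate is accepted when its score reaches
`20 + 8·ln(L)` for mate length L — the familiar local-mode short-read
threshold shape.  The gene maximizing the summed pair score wins; score
ties within one isodecoder go to the lexicographically smallest name
(immaterial after isodecoder aggregation), and ties across isodecoders
are discarded as ambiguous and counted separately.

The engine is `Bio.Align.PairwiseAligner` behind two score-exact
shortcuts: an exact-substring mate scores 2L without running the aligner
(the attainable optimum), and near-exact mates are aligned only against
entries sharing one of three exact read chunks — an entry containing no
chunk sits at least 10 score points below a one-error candidate, and the
code falls back to the full scan whenever that margin is not met.  The
test suite checks the production path against an independent brute-force
numpy dynamic-programming oracle on ten thousand simulated pairs.

The charging call reads the observed bases covering the last three
aligned reference positions of the fragment: suffix `CCA` → charged,
`CC` → uncharged, anything else → undetermined.  Which mate supplies
those bases: under the fixture layout R2's first post-barcode base *is*
the ligation point, so R2 carries the signal whenever its own terminal
base is part of its alignment.  Only when that base was clipped (a
sequencing error at the terminus makes the local alignment end early)
does the package compare mates and let the one reaching the 3'-most
reference position win (ties: fewer mismatches in the terminal window,
then R2).  An earlier rule that always preferred the larger reference
end-point proved wrong in testing: a 1-9 nt barcode read-through on R1 —
too short for the trimmer's minimum overlap — can start with `A` and
spuriously extend R1's alignment over the reference's terminal A, faking
a charged end.  Anchoring on R2's ligation point removes that artifact
without weakening the suffix rule.

A stricter `end_anchored` mode additionally requires the fragment to
reach the reference 3' end (position L for `CCA`, L−1 for `CC`); it is
off by default because internal fragments are rare in these short
references and the plain suffix rule is the assay's published logic.
Pre-aligned SAM input is accepted as an alternative front end; the same
suffix rule is applied to the terminal aligned bases of each pair.

## Normalization and statistics

Per-sample counts are scaled by `mean(classified totals) / (sample's
classified total)`, so all samples share the cross-sample mean total.
The coefficient uses classified (charged + uncharged) totals because only
those enter downstream sums; a `mapped` basis is available.  The fraction
charged is invariant to this scaling — the coefficient multiplies
numerator and denominator — and the suite asserts that invariance to
1e-12.

Fractions are computed per sample per isodecoder by summing normalized
charged and uncharged counts over the isodecoder's genes.  A zero
denominator yields a missing value, never 0, and missing cells are
excluded from group statistics rather than imputed.  Condition summaries
are the arithmetic mean ± sample SD (n−1) over replicates.  Contrasts use
Welch's unpaired two-sided t-test (Welch-Satterthwaite degrees of
freedom) with Benjamini-Hochberg step-up adjustment applied across
isodecoders *within* each contrast — the many isodecoders tested per
comparison are the multiple-testing family; contrasts are not pooled.
Zero-variance degeneracies are defined explicitly: equal means → t = 0,
p = 1; unequal means → p = 0, flagged.  A ΔΔCt helper
(`relative abundance = 2^(−ΔΔCt)` against a reference gene and control
group) covers the companion qPCR analysis.

## The synthetic-data generator

The simulator is the package's substitute for deposited sequencing data
and defines the default study conditions: 3 conditions (`vehicle`,
`GCN2iB`, `GCN2iB_EAA`) × 4 replicates, 5,000 read pairs per sample,
read length 75, substitution error 0.002/base, 5% of pairs with an
unlisted barcode, 2% empty-adapter pairs (inserts of 5-15 nt).  Twelve
isodecoders (two gene copies each, one exact duplicate planted to
exercise deduplication) get baseline charging drawn once from 0.80-0.95;
His-GTG is perturbed — 0.92 / 0.55 / 0.88 across the three conditions —
reproducing the depressed-then-restored pattern of a GCN2-inhibition /
amino-acid-rescue experiment.  The numeric fractions are fixture choices,
not measured values.

Per pair the generator samples an isodecoder uniformly, a gene uniformly
within it, and the charged state as a Bernoulli draw from the condition's
profile; charged inserts are `gene + CCA`, uncharged `gene + CC`.  All
randomness flows from one seed (per-sample substreams plus a pooling
shuffle), making output byte-identical across runs.  Two deliberate
idealizations: the five barcode bases are emitted error-free, so the
unassigned rate equals the configured no-barcode fraction exactly rather
than drifting with the error rate; and error is substitution-only.  Not
emulated at all: PCR duplication, ligation bias, RT drop-off,
modification-induced misincorporation, abundance differences between
isodecoders, and indel sequencing error.  Passing tests therefore show
the pipeline recovers truth under clean library chemistry; they do not
certify behavior under modification-heavy real tRNA data, where
classified fractions are known to be far lower (~86% in published data
versus >99% here).

## Problem sizes and numerical choices

The test suite runs the default study end-to-end at its native size
(60,000 pairs), measures detection power over 100 independent end-to-end
simulations, checks classification exactness on ~100,000 error-free
fragments, and compares the aligner with the brute-force oracle on
10,000 pairs against a 20-gene panel — sizes chosen so each property is
measured at the scale its variance requires.  Type-I control is checked
over 500 repeats of the Welch test under a binomial global null.

Known limitation: Welch's test with four replicates per group is mildly
conservative — its empirical level is ~0.04 at nominal 0.05, a
small-sample property reproduced exactly by the scipy reference
implementation.  Detection of the default perturbation is unaffected
(power ≈ 1), but users comparing subtle charging shifts at n = 4 should
expect slightly sub-nominal false-positive rates rather than exact
calibration.

Other numerical conventions: coordinates are 0-based half-open on the
tRNA sense strand (R2 is reverse-complemented before use); normalization
requires every sample to have a nonzero classified total and fails
loudly otherwise; SD uses the n−1 denominator; BH passes NaN p-values
through without counting them toward the family size.
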