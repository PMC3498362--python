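# Methods

This note records the models, conventions and numerical choices behind
`nutrimir`, and what the synthetic-data tests do and do not demonstrate.

## Preprocessing

A raw read is trimmed at the leftmost full occurrence of the 3' adapter; if
none exists, at the longest adapter prefix (≥ `min_overlap`, default 8) that
ends flush with the read. Reads carrying the 5' adapter are treated as
ligation artifacts and dropped when a 5' adapter is configured. Inserts
outside the length window are rejected with a reason (`too_short`/`too_long`);
the window defaults to [18, 30] nt — wide enough to keep everything a
20–30-nt gel purification can yield — and the canonical 19–24-nt fraction is
computed afterwards from the length profile rather than enforced by the
filter. All sequences are normalized to the DNA alphabet (U→T) on input, since
matching happens in genome space. Trimming conserves reads exactly: collapsed
counts plus rejection tallies equal the raw read count, and the test suite
asserts this as a property.

## Mapping

Tags are placed by exact substring match on the forward strand and by exact
match of the reverse complement on the reverse strand; no mismatches, gaps or
splicing. The index is a 15-mer seed table with literal verification, so
every reported locus is correct by construction and the whole mapper is
testable against a naive two-strand scan (the suite does this on multi-kb
genomes, including homopolymer regions where placements overlap). `N` bases
never match. Coordinates are 0-based half-open internally; GFF3 conversion
(1-based inclusive) happens only in the readers/writers. Multi-mapping tags
are counted once per tag in all composition and expression tables, with the
locus count carried along; discovery additionally caps candidates at
`max_nloci` (default 5) placements.

One consequence of perfect-match mapping worth knowing: a miRNA hairpin locus
contains the mature's exact reverse complement on the opposite arm, so every
mature tag maps twice — once on each strand. Discovery deduplicates the
resulting mirror clusters (see below).

## Composition and overlap summaries

A tag inherits the class of any structural-RNA feature one of its loci
overlaps by ≥1 bp on the same strand (strandedness configurable), with the
fixed precedence rRNA > tRNA > snRNA > snoRNA deciding multi-class overlaps;
classification is therefore independent of annotation order. Percentages in
the composition table print with 2 decimals below 10% and 1 decimal at or
above 10%, matching the mixed precision such summary tables conventionally
use. Feeding the published per-class read totals through this arithmetic
reproduces the published library totals and the tRNA/other cells exactly; the
rRNA percentage cells do not reproduce from their own printed counts
(307668/9681350 = 3.18%, printed 3.12%; 281621/10285363 = 2.74%, printed
2.73%), so this implementation stands behind the computed values and treats
those two cells as discrepancies in the source. Library overlap calls a
sequence common iff it has nonzero counts in both conditions; the read-level
percentages use the combined total of both libraries as denominator, with
common sequences contributing counts from both sides.

## Quantification and response classes

A tag contributes to a mature miRNA only on full-length exact identity —
this is what makes single-nucleotide family-member resolution possible — and
members with identical matures are merged into one group whose name
compresses consecutive suffix letters (`miR169d-g`). RPM = count / library
total × 10⁶, reported to 2 decimals. The fold change is
`log2(count_B/count_A)` on raw counts, with +1 added to both counts only when
either is zero (this preserves exact reproduction of nonzero published count
pairs while keeping the statistic finite); rounding is half-away-from-zero to
1 decimal. Raw counts rather than RPM are used for the novel-candidate table
because recomputation shows raw ratios reproduce the published fold column
(e.g. log2(82/1145) = −3.80) while per-million-normalized ratios do not
(−3.89); RPM mode remains available. Of the 20 published count pairs, 19
reproduce the printed fold to 1 decimal; the remaining one prints 2.4 where
log2(153/28) = 2.45 rounds to 2.5 under every standard rule, so it is
documented as unexplained rather than chased with a bespoke rounding.

Response classes use strict inequalities: induced (NSI) iff
log2fc > log2(threshold), suppressed (NSS) iff log2fc < −log2(threshold),
else unchanged; thresholds default to ratio 3 for known miRNAs and ratio 2
for novel candidates (applying the ratio>2 rule to the 20 published pairs
yields exactly 9 responsive candidates, which the suite asserts). Records
with combined counts below 5 are flagged `low_count` and receive no call —
a declared, configurable floor; the source notes miRNAs with counts below 10
without stating a filter. No count-model significance test is attempted: the
published analysis is fold-threshold-based, and adding one would change the
scientific contract.

## Secondary structure and hairpin criteria

The default folding engine maximizes summed pair weights (G:C = 3, A:U = 2,
G:U = 1) over nested structures with a minimum hairpin loop of 3 unpaired
nt — a weighted Nussinov dynamic program with a fully deterministic
traceback (ties prefer leaving the 5' base unpaired, then the smallest
partner). Its optimum is verified against exhaustive enumeration for all
tested sequences up to length 14. A thermodynamic MFE folder can be plugged
in through the same `(sequence) -> (dot-bracket, score)` contract but is not
required by anything in the package.

Candidate loci are single-linkage clusters (merge distance 30 nt per strand)
of unannotated ("other"-class) tags that match no known mature, are 20–24 nt
long, have combined counts ≥ 5 and ≤ 5 genomic placements. For each cluster
two windows are excised — long flank 150 nt on one side, short flank 20 nt
on the other, in both orientations — so the mature can sit near either arm
of a typical plant precursor; minus-strand windows are reverse-complemented
so the mature reads 5'→3'.

A candidate passes when, in a folded window, the mature (a) lies in one arm —
all partners of its paired bases on one side, across the terminal loop;
(b) has ≤ 4 unpaired bases; (c) contains no unpaired run longer than 2;
(d) does not span across the terminal loop (a 1–2-nt dangle into the loop is
normal and allowed — the unpaired/bulge budgets police it); and (e) forms a
*coherent* stem: at least `L − 4` of its partners lie within ±2 of one
antidiagonal `p + partner(p)`. Criterion (e) is this package's addition to
the classic annotation criteria and exists because a base-pair-maximization
fold pairs nearly everything in a 190-nt window; without it, scattered
one-sided pairing lets a few percent of random decoy windows through, and
with it the planted/decoy separation in the test suite is clean. When the
global fold of both windows buries a genuine duplex in diffuse pairing (this
happens — a perfect 21-bp stem is not always part of the weight-maximal
structure), a duplex-anchored fallback scans the ±150-nt neighbourhood for
the best antiparallel complementary arm of the mature and evaluates that
explicit stem-loop helix, in the spirit of miRDeep's duplex check. Among
passing windows the highest pairing score wins, then the longer stem.

Because both strands of a hairpin locus yield mirror candidates, candidates
with overlapping windows on the same chromosome are deduplicated, preferring
star-supported, then higher-scoring, then plus-strand candidates. Clusters
within the merge distance of any locus of a known mature tag are dropped —
otherwise a known miRNA's star reads would resurface as "novel" candidates.

The star interval is derived from the duplex geometry: with the stem's modal
antidiagonal `D` (exact for contiguous stems, robust to stray pairs),
`partner(x) = D − x`, and shifting both partner ends by +2 realizes the
canonical 2-nt 3' overhang on both duplex ends. Re-deriving the mature from
the star's interval returns the original mature interval, which the suite
asserts. Star support means some tag equals the star sequence within ±1 nt
at either end; it is reported, never required for candidacy.

## Target prediction and degradome grading

Targets are scored by an ungapped antiparallel alignment of the miRNA
against every window of its length in each transcript: Watson–Crick 0,
G:U wobble 0.5, otherwise 1; sites at or below penalty 3.0 (the
"three mismatches or less" contract) are reported. A strict Hamming mode
(G:U = 1) is available; note the wobble-scored penalty is *not* invariant
under reverse-complementing both strands (G:U complements to A:C), only the
Hamming penalty is. Slicer cleavage is expected at the transcript position
opposite miRNA nucleotide 10, i.e. `t₁ + L − 10` for a site starting at t₁;
degradome tags within ±1 of that position are summed and graded: category 4
if the evidence is a single read; 0 if it matches a unique transcript-wide
maximum; 1 if a tied maximum; 2 if above the median of nonzero positions;
3 otherwise; `none` without support. The category scheme is a declared
CleaveLand-style convention — the source reports only per-site read counts.

## The synthetic study generator

`synthio` emulates the study design: a random genome carrying planted
hairpin cassettes (mature + 8-nt loop `AACAAGAA` + reverse complement, so a
qualifying stem exists by construction, with the star overlapping the 3' arm
plus 2 nt of flank), structural-RNA loci of all four classes, decoy loci,
and a transcriptome with perfectly complementary planted target sites.
Planted effects default to a palette spanning −3.8 … +2.5 (both signs and
zero); mature lengths concentrate on 21 nt within 20–24. Read counts are
negative binomial with variance μ + αμ², α defaulting to 0.1 — a modeling
choice, not a source value, since no per-library dispersion is derivable
from the published tables; α = 0 degenerates to deterministic counts equal to
the expectations, which makes every downstream rate analytically checkable.
Background tags (4 per structural/decoy locus, length profile placing ~90%
of reads in 19–24 nt) are drawn once and emitted with equal expected counts
in both conditions, so any false response call is attributable to sampling
noise alone. The expected condition-A total matches the configured depth;
condition B deviates by the planted effects, as in a real experiment.
Background tags are screened against chance inverted repeats (any
near-complementary partner with ≥ L−6 pairable positions within ±200 nt
triggers resampling): random sequence contains genuine hairpin loci at a
low rate, and a "decoy" that actually folds is not a decoy. Degradome tables
place a fixed-height peak at each planted cleavage position plus uniform
unit-count noise at a configurable per-position rate.

What passing recovery tests show: the pipeline's logic is internally
consistent and recovers planted truth under the stated noise model. What
they do not show: robustness to sequencing error, adapter variants, RNA
editing, isomiR heterogeneity, expression-dependent folding artifacts, or
genome-scale multi-mapping structure — none of which the generator emulates.

## Problem sizes and determinism

The recovery configuration used by the acceptance script plants five
|log2 fold| = 2 effects at base mean 200 with α = 0.1 and 200k reads per
library on a 2×30-kb genome — large enough that every stage (including
~30 precursor folds at ~190 nt) runs in seconds while the planted effects
sit well clear of the response threshold. All randomness flows from a single
integer seed through separate derived streams for reference construction,
library sampling and degradome noise; fixed seed means byte-identical
outputs, which the suite asserts end to end.

## Known limitations

Base-pair maximization is not a free-energy model: its structures over-pair
and should be read as "a qualifying duplex exists", not as the thermodynamic
fold; the stem-coherence criterion and anchored fallback compensate, and an
MFE plug-in is the natural upgrade. Perfect-match mapping discards
SNP-bearing and edited reads by design. The target model is ungapped with
position-independent costs (no seed-region weighting, no bulged targets).
Family aggregation requires an explicit member→family map rather than
inferring families from names.
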