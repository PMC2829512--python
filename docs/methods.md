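# Methods

This note documents the models, algorithms, parameter defaults, and design
choices behind `evoreseq`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Study system emulated by the generator

The package targets clonal ancestor/evolved strain pairs from microbial
experimental evolution, resequenced with single-end short reads.  The
synthetic generator reproduces the architecture such experiments have
revealed:

- a haploid reference of 100–500 kb (default: one 200 kb chromosome at 38%
  GC, i.i.d. bases) standing in for a compact nuclear genome;
- a small set of clonal SNPs (default 4), placed ≥ 1 kb from chromosome
  ends, ≥ 100 bp apart, and ≥ 2 kb away from the amplified region so allele
  fractions stay clean;
- one tandem-inverted amplification: the segment S = [left, right]
  (default 11,038 bp) is replaced by the alternating-orientation array
  S(+), S(−), S(+), … with k copies (default 5).  For odd k the outer flank
  junctions read as wild-type sequence — exactly the situation in which
  junction-spanning wild-type reads coexist with inversion junctions;
- 36 bp single-end reads at 35× (evolved) and 28× (parent) with 0.5%
  per-base substitution error, drawn uniformly from both strands, constant
  high quality (the callers are count-based, not quality-based).

### Junction construction and micro-homology

Short inverted-repeat arms are planted in the *reference* flanks (they
belong to the ancestor — the rearrangement forms through them):

- left arm: `ref[left−s_L−h_L .. left−s_L−1] = revcomp(ref[left .. left+h_L−1])`
- right arm: `ref[right+s_R+1 .. right+s_R+h_R] = revcomp(ref[right−h_R+1 .. right])`

with defaults h_L = 7, h_R = 13 and spacers s_L = 6, s_R = 10.  Each
inverted junction of the evolved chromosome runs forward through the
proximal arm and continues leftward (reverse complement) from just below the
distal arm.  A sequence crossing the junction therefore aligns back to the
reference as two ungapped opposite-strand pieces whose contig intervals
overlap by exactly h: the arm bases are claimed by both pieces, which is the
defining signature of micro-homology-mediated inverted junctions.

Two details make the planted homology *exactly* h rather than "at least h":

1. **Terminator bases.**  Micro-homology length is the maximal shared
   sequence, so the bases delimiting each arm are forced to mismatch the
   continuation they would otherwise extend (a chance match occurs with
   probability 1/4 per boundary and would genuinely lengthen the homology).
   For the same reason a non-zero arm requires spacer ≥ 1 — abutting arms
   form a longer palindrome.
2. **Strict mismatch bridging in the aligner** (below).

The generator's truth record (`TruthSet`) stores the planted SNPs, the
amplification coordinates/copy number/structure label, and the junction
sequences cut from the evolved chromosome; the junction sequences are
required (and tested) to re-classify with the planted overlap lengths.

## Mapping and mappability

The internal mapper places reads ungapped on either strand with at most 2
mismatches (read length 36), via an exact full-window hash plus a pigeonhole
seed search (three 12-mer seeds cover every ≤ 2-mismatch placement).  Reads
with two or more equally good best placements are retained but classed
`multi_zero` and excluded from all depth and pileup statistics — the same
role the mapping-quality < 10 filter plays for externally aligned data,
which enters through SAM (`read_sam`, MAPQ < 10 demoted).  Ties are never
assigned arbitrarily.

A reference position is *mappable* iff its read-length window occurs exactly
once in the genome counting both strands; windows overrunning a chromosome
end are unmappable.  The window is anchored at the position, matching read
placement semantics.  All SNP, depth, and CNV statistics are restricted to
the mappable nuclear genome; chromosomes named like a mitochondrion
(`chrM`, `MT`, …) are excluded from totals and segmentation.

## SNP heuristic

A position is called iff it is mappable, evolved depth ≥ 6 with a single
base at ≥ 80% of calls, and parent depth ≥ 5 with a *different* base at
≥ 70% of calls.  Thresholds are inclusive; an evolved 3/3 tie fails the 80%
test by construction.  `callable_fraction` reports the fraction of mappable
positions meeting both depth thresholds (at 35×/28× Poisson-like coverage
this exceeds 0.99; the tests assert > 0.95).  A parallel quality-score
filter scheme exists in the field but its thresholds are not standardized;
the heuristic here is deliberately count-based only.

False-positive control comes from the concordance requirement: with ≤ 1%
error, a spurious call needs ≥ 80% *identical* errors at ≥ 6× — per-site
probability far below 10⁻¹⁰, so a 200 kb genome yields none (tested).

## Indel screen

Unmapped reads are split into two ordered, same-strand ungapped pieces
anchored by exact 12-mer seeds at the read ends: a reference gap between the
pieces is a deletion, a read gap with contiguous reference an insertion.
A candidate coordinate requires ≥ 2 supporting reads in one strain
(the smallest reading of "multiple"; configurable), no wild-type-spanning
reads in that strain, and wild-type-spanning reads in the comparison strain.
Micro-homology at a deletion junction shifts the reported coordinate by up
to the homology length (the split is canonicalized to the maximal suffix
extension).  Inversion-junction reads never qualify — their pieces land on
opposite strands.

## Copy-number analysis

Depth is averaged over 25 bp bins of mappable positions and normalized by
each strain's total nuclear bases; the per-bin log₂ ratio
(evolved/parent) is then **median-centered**.  Centering matters at toy
scale: a 5× 11 kb amplification on a 200 kb genome adds ~22% to the evolved
read total, biasing the raw segment ratio to ~4.1; on a megabase genome the
same effect is < 1%.  The median over usable bins is the flank level
whenever the amplified fraction is below one half, so centering restores
the baseline to 0 and the segment mean to log₂ k without affecting scale
equivariance.  Bins with no mappable positions or zero parent coverage are
flagged unusable and excluded (no pseudocounts — a ratio is never fabricated
where there is no data); a final partial bin needs ≥ half a bin of mappable
positions.

Circular binary segmentation is implemented from its published description:
over all circular arcs of a chromosome's usable-bin series, find the arc
maximizing |t| of arc mean vs complement mean with pooled variance (scanning
contiguous arcs suffices — an arc and its circular complement give the same
|t|).  The arc is split out if significant under a permutation null
(values permuted within the segment, max |t| recomputed; α = 0.01, 1000
permutations, seeded generator), and the recursion continues on each piece.
Numerical details:

- the O(n²) arc scan is a numba kernel that compares t² as a
  numerator/denominator pair, so the inner loop is division- and sqrt-free
  (~80 ms for 8000 bins; the dominant cost is the 1000-permutation null of
  the first split, ~1–2 min for a 200 kb genome at 25 bp bins);
- the permutation loop stops early once the exceedance count can no longer
  stay within α (a non-significant segment costs ~α·n_perm permutations);
- a zero-pooled-variance arc on a non-constant series is a *perfect* split
  and wins with infinite t; a fully constant series returns the t = 0 flag.
  Degeneracy thresholds are scale-relative (1e-10 of the total sum of
  squares) because exact cancellation cannot be assumed in floating point;
- ties in the arc scan break to the smallest (i, j).

Smoothing merges adjacent segments whose means differ by less than
3 × SD_residual, where SD_residual is the chromosome-wide SD of usable-bin
ratios about their segment means, recomputed until stable ("3 standard
deviations" could also be read as the global bin SD; the residual reading is
adopted and the multiplier is configurable).  Segments spanning < 1000 bp
are then absorbed into the more similar neighbor.  Reported breakpoint
uncertainty is ± one bin width (± 25 bp at defaults); the detected
boundaries additionally carry the spacer-sized offset of the amplified
footprint (the inverted copies extend spacer bases past the nominal segment),
which is below bin resolution at the defaults.

## Breakpoint recovery

**Assembly.**  Unmapped reads are assembled in a de Bruijn graph over
*both strands as a directed graph* — every read contributes its own and its
reverse-complement k-mers, and unitigs are deduplicated against their
reverse complements afterwards.  Canonical-collapsed nodes were rejected
deliberately: an inverted-tandem junction contig contains a sequence and its
reverse complement a few bases apart, and collapsing them creates a spurious
branch inside every junction contig.  The mirror branch still splits the
walk ~k−1 bases past the spacer, so junction unitigs span the junction by at
least spacer + k − 1 bases on their short side — ample for two-part
alignment at k = 21.  k-mers seen once are pruned (at 0.5% error a 36 bp
read yields singleton error k-mers; true junction k-mers are covered by
~25–50 reads at 35×), and unitigs shorter than 40 bp are dropped.  Output
order is deterministic (length desc, then sequence).

**Split alignment.**  Contigs are aligned ungapped on both strands by exact
12-mer seeding and per-diagonal extension.  Extension is exact-match
greedy; a mismatch is crossed only when followed by ≥ 12 exact matches.
The strict bridge is load-bearing: the spacer between inverted-repeat arms
reads as a near-palindrome, and with a permissive bridge (e.g. 4 matches)
the alignment reads straight through the junction and inflates the measured
overlap (observed: 7 → 20 in about a quarter of random genomes).  The
spacer interior can supply at most spacer − 2 chance matches, so any bridge
larger than the spacers in play keeps junctions tight while still absorbing
isolated interior mismatches.  Alignments shorter than 18 nt are discarded
(random exact 12-mer hits would otherwise occasionally add a third,
spurious alignment to a junction contig); retained alignments must reach
90% identity.

**Filters** (all three from the contig side): (a) contigs fully explained by
one reference region (a single alignment covering ≥ 95% of the contig) are
removed; (b) both end-anchoring alignments must land at mappable reference
positions; (c) the alignments must cover ≥ 90% of the contig's bases.

**Classification.**  For a two-part contig, parts are ordered by contig
interval; the orientation class is `inverted` iff the strands differ, and
the micro-homology overlap is lenA + lenB − contig length (computed from
contig-interval lengths, never from reference coordinates, whose
inclusiveness conventions are ambiguous at junctions).  Junction reference
coordinates are the inner alignment ends; the micro-homologous bases belong
to both parts by nature.  A call is in-amplification when its nearer inner
coordinate falls within the segment boundaries ± uncertainty — the farther
coordinate legitimately lies spacer + homology beyond the boundary.

**Wild-type support.**  A coordinate has wild-type support iff ≥ 1
uniquely-mapped read covers [coord − 10, coord + 10] matching the reference
exactly in that window.  For odd copy numbers the outer flank junctions are
wild-type and support holds at both boundaries; a clean deletion boundary
has none.

**Background probability.**  With n_bg filtered junction-like contigs found
in the *ancestor* (which carries no amplification), the per-mappable-base
rate is r = n_bg / N_mappable and the probability that background contigs
land inside the two boundary windows is P = (r × w)^2 with w = 50 bp
(± 25 bp), capped at 1.  The two windows are treated as independent and
equal-sized.  Only nuclear-aligned contigs enter the estimate; contigs
aligning to non-nuclear chromosomes are tabulated but excluded (their depth
regime differs).

**Structure inference.**  The label `tandem_inverted` requires: both
boundary calls inverted-class, both in-amplification, and wild-type support
at both boundaries; anything else is `unresolved` with the evidence listed.
Direct-orientation boundary calls (a simple tandem duplication) are
deliberately outside the label's definition.

## Defaults

| parameter | default | notes |
|---|---|---|
| read length | 36 bp | single-end |
| mapper max mismatches | 2 | ungapped, both strands |
| MAPQ threshold (SAM) | 10 | below → `multi_zero` |
| SNP thresholds | 6×/80%, 5×/70% | evolved / parent, inclusive |
| indel min support | 2 | "multiple" reads |
| bin width | 25 bp | uncertainty ± 1 bin |
| CBS α / permutations | 0.01 / 1000 | seeded |
| smoothing | 3 × SD_residual | residual SD, recomputed |
| min segment span | 1000 bp | absorbed into neighbor |
| assembly k / cutoff / min contig | 21 / 2 / 40 bp | |
| contig identity / coverage | 90% / 90% | ungapped |
| seed length / min alignment / bridge | 12 / 18 / 12 nt | split aligner |
| wild-type span | ± 10 bp | |
| background window | 50 bp | per boundary |

## Problem sizes in the test suite

The full-scale scenario (200 kb, 35×/28×, 1000 permutations) runs once per
test session (~3 min); module tests use 20–60 kb genomes, 250–300
permutations, and direct Poisson depth tracks where only the segmentation is
under test.  Parameter-recovery properties run over 20 seeds (boundary
error and copy-ratio bias) and 10 seeds (junction recovery), chosen to keep
the whole suite within a normal CI budget while leaving every algorithmic
path exercised at full fidelity.

## What the synthetic tests do and do not show

The generator produces uniform coverage, i.i.d. errors, a repeat-free
random genome, and perfect-identity repeat arms.  Real data add coverage
waves (GC, origin effects), indel sequencing errors, genuine repeat
families (Ty elements, tRNA clusters, telomeres) that shrink the mappable
genome, and possibly heterogeneous (non-clonal) populations.  Passing tests
therefore demonstrate the correctness of the algorithms and their
interfaces under the stated model — thresholds appropriate for real genomes
(especially the SNP fractions and the CBS α) should be revisited per
dataset.  Mitochondrial structures surface in the contig tables but are
never interpreted; population-level (non-clonal) variant calling, gapped
contig alignment, and quality-score-based filtering are out of scope.
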