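# Methods

## Cleavage model

SpCas9 guided by a 20-nt protospacer adjacent to an NGG PAM cuts
predominantly bluntly between protospacer positions −3 and −4 (counted
from the PAM; −1 is PAM-proximal).  A substantial minority of cleavages
are staggered: the non-target strand is cut 1–3 nt further PAM-distal,
leaving a 5′ overhang over positions −4 to −6.  Fill-in of a k-nt overhang
duplicates exactly those k bases at the junction.  `GuideSite` therefore
carries a blunt-cut inter-base coordinate plus `max_overhang` (default 3),
and `predicted_overhang(guide, k)` returns the bases at −4…−(3+k) on the
protospacer strand, PAM-proximal first.  Only the NGG dialect is accepted;
coordinates are 0-based, half-open, with cuts as inter-base integers —
this makes junction arithmetic exact and unambiguous.

A junctional reference is the predicted post-rearrangement sequence: an
upstream arm abutting a downstream arm at the junction coordinate.
Geometries: deletion (left flank of cut 1 + right flank of cut 2),
inversion junctions (one flank + the reverse complement of the fragment
flank), duplication (left flank of cut 2 + right flank of cut 1 — the
seam between tandem fragment copies; the published schematics for
head-to-tail duplications admit only this seam, which is the design
choice made here), and single-cut (the uncut segment, junction at the
cut).  Arms are trimmed to a 150-nt window per side so that junctional
amplicons, which are under 290 bp by design of such libraries, always fit
inside the reference.  Each arm records its PAM frame — the PAM-relative
position of the junction-adjacent base and the direction of travel — so
deleted bases can be reported as −4, −5, −6, … (PAM-distal flank) or −3,
−2, −1, +1, … (PAM-proximal flank; there is no position 0).

## Junction alignment

Each read is decomposed into a left part aligned to the upstream arm, an
optional unmapped middle insertion, and a right part aligned to the
downstream arm.  Two levels of optimisation: per-part affine-gap
alignments (lower level) and the choice of split indices (upper level).

Scoring (all configurable; integers by default so every DP value is exact
in double precision): match +1, mismatch −2, gap open −4 (first gapped
base), gap extend −1, each unmapped middle base −1, N always a mismatch.
Per part, the outer end is free on the arm (a read may start anywhere
inside an arm) and the junction-proximal end is free within the arm: the
distance from the alignment end to the junction is reported as
`del_up` / `del_down` and is *not* charged as a gap — deleted bases at
the cleavage site are the measurement, not an alignment artefact.
Internal gaps are ordinary affine gaps; insertions are only free-form at
the junction (the middle part).

The implementation computes, in one matrix pass per arm, the best score
of every read prefix against the upstream arm and (on reversed
sequences) every read suffix against the downstream arm, then maximises
`left(i) + right(j) + penalty·max(0, j−i)` over all splits with
`j ≤ i ≤ j + max_overlap` (default 6) or `i ≤ j`, with both parts at
least `min_anchor` (15 nt) long.  Overlapping read bases are scored in
both parts: sequence that genuinely matches both arms — the signature of
staggered ends — raises the score of the overlap decomposition, and
junction-flanking homology is absorbed symmetrically rather than being
attributed to one arm.  Ties are broken toward precise ligation: smaller
middle insertion, then smaller `del_up + del_down`, then larger overlap,
then the leftmost split.  A read maps when its optimum reaches
`0.6 · match · read_length`; both orientations are tried and the higher
score kept (forward on ties).

`brute_force_align` is the independent oracle: it enumerates every split
pair exhaustively and scores each part with Biopython's
`PairwiseAligner` (global on the read part, free end deletions on the
arm; its gap convention — a gap of length g costs open + (g−1)·extend —
was verified to match).  The test suite asserts score equality on 500+
constructed and randomised instances; this oracle contract, rather than
any particular constant, is what pins down the aligner's semantics, so
the scoring parameters can be varied freely in configuration.

## Outcome classification

Mapped alignments fall into four mutually exclusive groups from the
deleted and inserted base counts at the junction: precise (0, 0),
deletion (>0, 0), insertion (0, >0), indel (>0, >0).  Reads in the
"indel" group are not additionally counted in the deletion-size
histograms.  Deletion sizes are binned 1 / 2–20 / 21–100 / >100 bp;
deletions beyond 100 bp are tallied as large resections (the cutoff is
configurable; 100 bp is the boundary of the small-deletion analysis
window).  A 1–3 bp insertion is *templated* when it equals a flanking
guide's predicted overhang in either base order (PAM-proximal- or
distal-first) — the orientation in which a duplicated overhang lands at
an inversion or duplication junction is geometry-dependent, so both are
accepted and the matching guide and order are recorded.  Deleted bases
are mapped to PAM-relative positions per arm (upstream deletions in the
upstream guide's frame, downstream in the downstream guide's); the
position profile over 1–3 bp deletions makes the −4/−5/−6 bias of
staggered cleavage measurable.  Library tallies report counts and
frequencies over junction reads (they sum to one), the repaired fraction
(junction reads / total reads) and the large-resection fraction
(>100 bp deletion reads / total reads).

## Large-resection calling

Bait–prey reads are split into two segments, each aligned semi-globally
against a user-supplied locus window (never a genome index): the first
on the forward (bait) strand, the second on whichever strand scores
higher.  A read is deletion-type when the second segment maps strictly
downstream of the first with both forward, inversion-type when the
second maps to the reverse strand, otherwise unclassified.  Given the
two expected cut positions, the resected length is the sum of the
distances from each cut to the observed mapped boundary; junctions
losing more than 100 nt count toward the large-resection fraction.
Direct (non-resected) junctions whose flank boundary bases coincide are
ambiguous by ±1 nt in the boundary placement; this cannot affect the
class or the large-resection tally.

## Microhomology statistics

A deletion-sized region of n bp around the cut is split into two flanks
of n/2 (remainder to the upstream flank).  `M` is the longest common
*substring* (contiguous, matching the longest-run analogy; not a
subsequence) of the flanks, computed exactly by binary search over the
match length with bit-packed k-mer set intersection — O(n log n), so
Monte-Carlo runs at n = 2¹⁶ are practical.  The Arratia–Waterman bounds
on P(M ≤ L) and the derived MMEJ curve P(M ≥ 2) = 1 − upper(n, 1) use
log base 1/p computed as ln n / ln(1/p); the raw formulas leave [0, 1]
at small n and are clamped.  Two caveats worth stating plainly, both
verified numerically by the test suite: (i) the upper bound is not
monotone in p at fixed n and diverges as p → 0 (the clamp returns 1);
(ii) the bounds are asymptotic — at n ≲ 32 under the half-flank window
convention the empirical P(M ≤ 3) can slightly exceed the upper bound,
and the lower bound clamps to 0 for every L ≤ 3 at n ≤ 128, so sandwich
checks are only informative where both bounds are interior to (0, 1).
`simulate_M_ratio` draws uniform random flank pairs of n/2 symbols over
an alphabet of 1/p letters and reports the mean of M / log_{1/p}(n) with
its standard error.  The mean approaches the limit 2 from below; at
n = 2¹⁶ with flanks of n/2 it sits near 1.84 — the residual offset is
the finite-size term ≈ 1/log₄ n plus the extreme-value centring
constant, and vanishes only slowly with n.

## Simulator

The generator's defaults are the study conditions it emulates: amplicons
of ≤ 290 bp (read window 280 nt, 140 per arm), constant Q40 qualities,
substitution-only errors (Illumina amplicon error profiles are
substitution-dominated, and indel errors would make truth assignment
ambiguous), and an outcome mixture spanning precise ligations (0.35),
1 bp deletions (0.15), MMEJ deletions (0.20; microhomology length 1–4,
offsets 0–7 from the junction, deletion size = up-offset + down-offset +
homology length, reported left-aligned with the retained copy attributed
upstream), templated insertions (0.15; overhang length distribution
{1: 0.5, 2: 0.3, 3: 0.2}), random insertions (0.10; 1–8 nt), and large
resections (0.05; 101–220 nt).  A staggered-deletion class (`del_stagger`,
junction-adjacent 1–3 bp deletions with the same overhang-length
distribution) generates the −4/−5/−6 position-bias libraries.  The
bundled synthetic locus places the upstream guide on '+' and the
downstream guide on '−' (PAM-out), so both junction flanks carry the
−4/−5/−6 window.

Truth identifiability: an event whose clean read is consistent with a
different, preferred decomposition (e.g. a deletion flanked by
coincidental homology, which legitimately shrinks under the overlap
rule, or a random insertion that happens to equal a guide overhang) is
redrawn, after a fast boundary-base screen, by verifying that aligning
and classifying the error-free read returns exactly the intended event.
Real libraries do contain such inherently ambiguous molecules; simulated
ones deliberately do not, which is precisely what makes the count-level
round-trip checks (exact recovery at error rate 0; frequencies within
three binomial standard errors at error rate 0.01) meaningful.  What
passing these checks shows is internal consistency of the
simulate→align→classify loop under the stated conditions — not accuracy
on real data, whose error profiles, chimeras and PCR artefacts the
generator does not model.

## Problem sizes and numerical choices

Round-trip checks run at 5,000 reads per library; the oracle-equivalence
suite uses 500+ reads of ≤ 60 nt (the exhaustive oracle is quadratic in
the split indices); Monte-Carlo bound checks use 10⁴ flank pairs at
n ∈ {32, 64, 128} and 500 pairs at n up to 2¹⁶.  All randomness flows
through seeded numpy generators; simulation output is byte-identical for
a given configuration.  DP scores are integer-valued doubles, so
traceback equality tests are exact (a 1e-9 tolerance guards non-integer
custom schemes).

## Known limitations

- Reads extending past an arm window are penalised as gaps rather than
  soft-clipped; references should be built with arms covering the
  amplicon.
- Insertions are free-form only at the junction; a true insertion far
  from the cut appears as an ordinary alignment gap.
- The two-segment resection mapper considers one locus window at a time;
  genome-wide translocation discovery is out of scope.
- Adapter handling is fixed-prefix trimming (barcodes) only; pair
  merging is a naive best-ungapped-overlap consensus.
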