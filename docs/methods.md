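# Methods

## The element model

The canonical element is specified by `CanonicalElementSpec`: total length
916 bp; 23-bp TIRs whose inward reads (top strand on the left end, bottom
strand on the right end, both read outer edge → interior) are identical
except at np 17 (A in the left read, T in the right — the diagnostic
asymmetry); a −35 box TTGTCC at np 5–10, inside the left TIR; a −10 box
TATAAT at np 28–33, outside it, with the canonical 17-bp spacer; an 870-bp
transposase ORF. Insertion duplicates a 3-bp target site T(T/A)A, leaving
identical direct repeats flanking the element.

Geometry forces one compromise. Two 23-bp TIRs in a 916-bp element leave
exactly 870 bp of interior, yet an ORF filling that interior would place an
in-frame TAA stop inside the fixed −10 box (TATAAT read in the frame that
starts at np 24). The only stop-free frame through the box begins at np
≡ 25 (mod 3), so the ORF is placed at np 22–891: its ATG uses the last two
nucleotides of the left TIR (chosen as ...AT) plus the first interior base.
Transposase ORFs overlapping their TIRs are common in real IS elements, so
the builder permits up to 3 nt of overlap at either end.

### Generator guarantees

`build_canonical_element` fills all unconstrained positions randomly under
the seed (interior ORF codons are drawn from the 61 non-stop codons), then
enforces three guarantees so the synthetic truth is unambiguous for *every*
seed, not just lucky ones:

* **TIR boundary.** The two positions immediately interior to each TIR are
  forced to break complementarity with their partner positions. Without
  this, random filler extends the inverted repeat past 23 bp with positive
  probability, and a mismatch-tolerant detector would (correctly!) report a
  longer repeat.
* **Promoter uniqueness.** Filler is rejection-resampled (bounded retries)
  until the designed (−35 @ 5, −10 @ 28) pair is the scanner's top-ranked
  hit; a random 60-nt window produces a spurious higher-scoring pair in
  roughly 2% of draws.
* **ORF identity.** The designed ORF must come back as the longest ORF on
  either strand.

Constrained positions are byte-identical across seeds; filler varies.

## Inversion operators

* `full_ab`: reverse complement of the whole element (an involution).
  Excision/re-integration in inverted orientation and TIR-TIR recombination
  with the conversion tract upstream of the diagnostic mismatch produce the
  same sequence, so they are modelled — and later classified — as one
  outcome. Excision/re-integration is taken to regenerate the *same* TSD at
  the same site; whether re-integration could alter the direct repeats is
  not modelled (flagged as an open choice).
* `internal_c`: reverse complement of np 18 … len−17. The tract interval
  np 18–23 is identical between the TIRs, so any breakpoint inside it gives
  the same observable configuration; the innermost position is fixed for
  determinism.
* `conversion_left_d` / `conversion_right_e`: the internal inversion plus
  homogenisation of both inward reads to the left / right canonical read
  (only the diagnostic position actually changes).
* `excision`: element removed; the caller retains a single target-site copy,
  exactly restoring the never-inserted sequence context.

## Locus simulation

A locus is flank (300 bp) + target site + [element + second site copy] +
flank (300 bp). The strain tree is either supplied as newick or drawn from a
Yule process (height normalised to 1, so `mutation_rate` is substitutions
per site per tree depth). The insertion event is placed on the stem branch
of a monophyletic clade, the inversion (or excision) on the stem of a nested
subclade. Point mutations are Bernoulli per site per branch with probability
`rate × branch length`, replacement uniform over the other three bases —
a Jukes–Cantor-style neutral model with no indels besides the event-level
ones, sufficient for testing the detectors. Absence is encoded as one
contiguous gap block spanning element + second TSD copy, matching how such
alignments are rendered. With `protect_features` (default on, intended for
validation fixtures) mutations avoid the TIRs (including the two boundary
guard positions, which pin the detected TIR length), both promoter boxes and
their mirror images (the −10 box moves to the mirrored np after an internal
inversion), and the TSD copies; everything else, including most of the ORF,
remains mutable. Truth tables record per-strain states, events per branch,
element intervals and substitution counts (observed and expected), and the
same config + seed is byte-reproducible.

What the simulator does **not** emulate: realistic base composition,
indels/rearrangements unrelated to the element, alignment error (rows are
constructed aligned), partially deleted elements, or recombination between
*different* element copies (the pairwise-orientation predictor handles that
question analytically). Passing tests therefore demonstrate correctness of
the inference logic on clean, correctly aligned input, not robustness to
alignment artefacts.

## Annotation

* **TIR detector**: largest k in [10, 50] whose terminal k-mers are
  reverse-complementary with ≤ d_max (=2, the diagnostic mismatch plus one
  mutation) mismatches *and* whose innermost position matches — a repeat is
  delimited by its last matching column, otherwise any repeat bordered by a
  tolerated mismatch would be extended indefinitely. Reports the full
  mismatch catalogue.
* **ORF finder**: longest start(ATG/GTG/TTG)-to-stop reading frame on either
  strand, ≥ 300 bp including the stop; ties prefer + strand then leftmost.
* **TSD detector**: longest exact match (2–10 bp) between the end of the
  left flank and the start of the right flank; flags T(T/A)A (3 bp).
* **Promoter scanner**: exhaustive −35/−10 hexamer pairs within the first
  60 nt (the elements of interest carry left-TIR-proximal promoters), spacer
  15–19 bp. Consensus T\*T\*G\*ACA and T\*A\*TAAT\*, with the asterisked
  (conserved) positions read as the position *preceding* each asterisk:
  {1,2,3} for the −35 and {1,2,6} for the −10, exact; ≤ 2 mismatches
  elsewhere. The alternative reading (position following the asterisk) is
  rejected because it would disqualify the naturally annotated −35 TTGTCC,
  whose mismatches to TTGACA sit at positions 4 and 6. Ranking: matched
  consensus positions (0–12) desc, |spacer−17| asc, leftmost −35.

## Orientation and classification

Orientation is decided by the transposase ORF strand relative to the
reference strain, not by TIR order — an internal inversion (c) flips the
transposase while leaving the TIR configuration canonical. Presence uses the
non-gap fraction over the element columns (≤ 0.10 absent, ≥ 0.50 present,
else ambiguous; the thresholds are robust to ragged element edges, and
partially deleted elements fall into the ambiguous class). Classification
keys on the diagnostic np only; full 23-mer disagreement (point mutations)
is reported in the evidence trail without changing the class, since the test
hinges on the single asymmetric position. The classifier refuses canonical
TIR pairs with zero or multiple mismatches (no diagnostic asymmetry).
TSD state is surfaced in the annotation but deliberately not used to try to
separate outcomes a and b.

## Event reconstruction

Sankoff parsimony over states {absent=0, canonical=1, inverted=2} with
default costs: insertion 1, inversion 1 (both directions), deletion 1 (from
either carrier state), direct gain of an inverted element 2, diagonal 0. The
root is pinned to absent by default (gain is the derived condition;
overridable). Ambiguous orientation enters as the state set {1,2};
absent-vs-ambiguous presence as {0,1,2}. Backtrace ties resolve to the
lowest state index for reproducibility, and the number of co-optimal
assignments is reported so ambiguity is quantified rather than hidden.

## Problem sizes and numerical choices

The test suite validates the Sankoff implementation against exhaustive
enumeration over all rooted tree shapes with 2–6 leaves (1, 1, 2, 3, 6
binary shapes plus multifurcating stars) × all 3^n leaf-state combinations ×
all internal assignments; enumerating states on one labelled representative
per shape covers every labelled topology because relabelling is an
isomorphism. Scenario-recovery validation uses 20-strain panels: all five
operators mutation-free, plus 200 replicates at 0.005 substitutions/site
with protected features (the residual failures are premature stop codons in
the unprotected ORF interior that occasionally flip an orientation call).
The promoter scanner is cross-checked against a brute-force double loop on
1,000 random 200-mers, and the TIR detector against a naive full scan.
Floating-point cost comparisons use `np.isclose`; all randomness flows from
`numpy.random.default_rng` seeds, and derived seeds stay below 2^31.

## Known limitations

* The a/b ambiguity is intrinsic to sequence data; no attempt is made to
  resolve it from TSD state.
* Orientation calling needs a detectable ORF; heavily degraded elements are
  reported ambiguous and enter the parsimony step as free state sets.
* The simulator's alignments are indel-free outside the event-level gap
  block, so the coordinate-mapping code sees only clean gap structure.
* Conversion-tract length is classified only into the three interval
  classes the TIR configuration can distinguish.
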