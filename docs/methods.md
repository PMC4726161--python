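# Methods

## The detection model

A MITE is modeled purely structurally: a body of 50–800 nt whose first and
last `tir_len` (default 10) bases form an inverted-repeat pair with at most
`max_tir_mismatch` (default 1) non-complementary positions, flanked
immediately outside the body by two identical copies of a target site
duplication of 2–10 nt. No homology to known elements is used; everything
with this structure, enough copies and divergent flanks is reported. The
model deliberately excludes TIRs with insertions or deletions: the two arms
are compared position-by-position at a fixed length, so an indel in one arm
shifts every downstream pairing and fails verification. Elements whose TSD
was eroded by post-insertion mutation are likewise invisible, as are
families whose genomic copy number is below three — both are conservative
choices that trade recall for a low false-positive rate.

## The numeric screen and why it needs verification

Scoring A → 1, T → −1, C → j, G → −j makes complementarity algebraic: a
base and its Watson–Crick partner sum to zero, and no other valid pairing
does. For a left window at `i` and right window at `r`, the statistic
C = W(i) + W(r) (window sums via one prefix-sum pass) is 0 for a perfect
inverted repeat; each mismatched pairing replaces a zero-sum pair with two
scores whose sum has L1 norm exactly 2. The screen keeps pairs with
|Re C| + |Im C| ≤ `score_tolerance` (default 2, i.e. ≤ 1 mismatch).

The statistic is a sum, hence blind to position: an A·A pairing (+2) can
cancel a T·T pairing (−2), letting a 2-mismatch pair through with C = 0.
The screen is therefore only a pruning device; every surviving pair is
re-checked position-wise before TSD search. The suite constructs such
compensating pairs explicitly and asserts both halves of the behavior.

TSD search runs from the longest length (10) down and requires the two
windows to be *string*-identical, not merely score-identical — score
equality is multiset equality (it cannot tell `AT` from `TA`), which is too
weak for a direct repeat. The longest qualifying length is annotated, a
deterministic tie-break that yields the maximal structure.

Bases outside {A, C, G, T} (and, with `skip_masked`, soft-masked bases)
invalidate any window containing them rather than being expanded as IUPAC
codes. Chromosomes are scanned in 1 Mb chunks with an overlap of
`max_len + 2·tsd_max` so results are provably chunk-invariant; each
left-window start belongs to exactly one chunk core, so no duplicates
arise. The scan covers the forward strand only: the TIR + direct-repeat
structure is invariant under reverse complement (a property test asserts
the mirrored candidate set), so a second pass would only duplicate results.

## Lempel–Ziv complexity: variant and calibration

The complexity filter uses the LZ76 exhaustive-history parse: scanning left
to right, a phrase ends one symbol past the longest prefix of the remainder
that can be copied from the sequence already seen; the final, possibly
copyable, phrase is counted. The production implementation is the
Kaspar–Schuster algorithm; an independent literal substring-search parser
serves as the test oracle and the two are compared on 10,000 random
strings. The phrase count c(n) is normalized as c(n)·log₄(n)/n — the
4-letter alphabet makes a uniform-random sequence approach 1 — so the
0.675 cutoff sits well below typical-complexity sequence: measured on
random 300-mers, >99% score above the threshold (most near 1.0), while a
homopolymer of 100 scores 2·log₄(100)/100 ≈ 0.066 and short-period repeats
score far below the cutoff. The variant and normalization are this
package's calibration decision and both the threshold and the statistic
are config-exposed.

Complexity is evaluated on the MITE body (TIRs included, TSDs excluded).
The stretch rule is evaluated on each TIR arm independently — a run
crossing from arm into body does not count — and a dinucleotide run whose
two alternating bases are equal is simply a homopolymer and is caught
either way.

## Clustering semantics

Identity is matches divided by the *shorter* sequence's length; coverage is
the aligned span projected on the *longer* sequence divided by its length.
Alignment is global with free end gaps (match +1, mismatch −1, gap −2,
config-exposed). Clustering is greedy longest-first against family *seeds*
only — the strategy CD-HIT popularized — so membership is evaluated against
one fixed sequence per family and results are deterministic. A conservative
length prescreen skips alignments that cannot possibly reach the coverage
bound. The optional `cd-hit-est` backend maps the same two thresholds onto
`-c/-aS/-aL` and falls back to the internal clusterer with a logged warning
when the executable is absent.

## Flank validation and the match count

Flanks are 50 nt immediately outside each TSD copy, truncated only at
contig ends; truncated flanks are biased toward "divergent" because the
≥ 25-match threshold is absolute. Left flanks are only ever compared with
left flanks, right with right. Members are processed in genomic order and a
member conflicting with an already-retained member is dropped; dropped
members do not disqualify later ones, which reproduces the canonical
worked case of five copies with two similar pairs reducing to exactly
three survivors.

One numerical subtlety: optimal-score alignments are not unique, and
co-optimal alignments of the same pair can differ substantially in how many
identical columns they contain — the count can even depend on argument
order. The match count is therefore defined as the identity count of the
first optimal alignment of the lexicographically ordered pair, which makes
it symmetric and reproducible; the same definition is used by the pipeline,
the synthetic generator and the invariant checks. Under this definition two
random 50-mers reach 25 matches with probability ≈ 0.05, which is why the
generator verifies planted flank pairs and re-randomizes violators instead
of relying on randomness alone.

Representative selection maximizes the summed pairwise optimal local
alignment score (match +2, mismatch −3, gap open −5, extend −2,
config-exposed); the sum (rather than mean) is irrelevant to the argmax at
fixed family size. Ties break by (sequence id, start), ascending.

## What the synthetic generator emulates — and what it does not

`generate_planted_genome` plants families into a uniform-random background:
each family has one seed body (random TIR arms that pass the composition
and stretch rules, a random spacer resampled until the body clears the
complexity threshold and contains no secondary candidate structure), and
copies that differ by spacer-only substitutions at 2% per base — TIR arms
and TSDs are untouched, so every planted copy remains detectable with
exact boundaries. Copies are placed at non-adjacent loci (≥ 140 nt apart)
and the generator then actively enforces three truths the tests rely on:
the annotated TSD cannot extend into a longer chance repeat, no chance
"shadow" candidate overlaps ≥ 80% of a planted body (such a structure
could join the family and displace a true copy during flank filtration),
and all within-family flank pairs fall below the 25-match threshold.
Designed negatives — 2-copy families, identical-flank families,
low-complexity (periodic-spacer) bodies, non-`TA` dinucleotide TSDs and
2-mismatch TIRs — are constructed to fail exactly one stage each.

A planting constraint worth knowing: a TSD whose interior contains a
direct repeat (which includes *every* TSD of length ≥ 4, via
tsd[1:-1] = tsd[1:-1]) cannot be planted cleanly, because shifting both
arms outward by one base keeps nine complementary pairings — within the
one-mismatch allowance — and finds that interior repeat as its own TSD,
creating an intrinsic off-by-one twin of the planted element. The
generator refuses such TSDs explicitly rather than emitting ambiguous
truth; detection of such structures in real genomes is unaffected (both
the element and its twin are reported, and clustering's coverage rule
keeps them apart).

Real genomes are not uniform-random: they contain nested and fragmented
elements, tandem repeats, segmental duplications, autonomous partners and
GC heterogeneity, none of which the generator models. Passing the planted
tests therefore demonstrates correctness of the pipeline's logic and exact
coordinate arithmetic, not field performance on real chromatin. The
background-only runs (no planted elements → zero families) show that the
copy-number and flank rules suppress chance structure in random sequence,
which is a weaker statement than specificity on real repeat-rich genomes.

## Problem sizes and numerical choices

The default verification workloads are sized for a desk-scale run: oracle
equivalence on 100 random sequences up to 2 kb, LZ agreement on 10,000
strings up to 1 kb, planted recovery on one 200 kb genome (10 families ×
5 copies) plus five 100 kb background genomes. A full-genome run mode is
the same code path (chunked scanning holds memory flat), only slower.
Coordinates are 0-based half-open internally and 1-based inclusive in every
emitted file. All randomness flows from explicit integer seeds; reruns on
identical inputs are byte-identical, which the suite asserts at file level.

## Known limitations

- TIRs with indels, and elements whose TSDs no longer match exactly, are
  undetectable by design.
- One TIR length per scan (default 10): arms longer than configured are
  detected via their terminal 10-mers, but the annotated TIR length is the
  configured one.
- Flank filtration keeps the first member in genomic order, which is a
  deterministic but arbitrary choice among conflicting members.
- The greedy seed-based clustering is order-dependent by construction
  (longest first); a different visiting order could split borderline
  families differently.
- The `cd-hit-est` cross-check requires the external binary and is skipped
  (with a warning) when absent.
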