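# Methods

## Model

An alignment is scored as the sum of substitution scores over matched
columns, gap penalties over maximal gap runs, and a motif term: a
bonus α is added for every matched column whose two positions are
annotated by at least one *common* motif pattern accession.  "Same
motif" is deliberately interpreted at the accession level, not the
match-instance level — match instances are not comparable across
sequences, and conservation of a motif means conservation of its
pattern identity.  The bonus applies only on match steps; it never
offsets gap costs.

Scores are carried as floats (α need not be integer); substitution
matrices are the integer NCBI tables (BLOSUM62 by default, BLOSUM40
and BLOSUM30 also loadable by name for low-identity families).

### Gap model

Penalties are non-positive.  Linear gaps cost `g(l) = d·l`; affine
gaps `g(l) = e + d·(l−1)` with the open penalty e charged at gap
birth (defaults e = −11, d = −1, the standard BLOSUM62 pairing).
The optimized kernel is a three-state (match / gap-in-A / gap-in-B)
Gotoh DP; linear is run as affine with e = d.  A cubic-time kernel
maximizes the general recurrence for arbitrary `g` with `g(0) = 0`
and serves as the reference implementation; for affine g with e ≤ d
the two provably coincide (splitting a gap run can never help), which
the test suite checks exhaustively.

### Semi-global mode

Terminal gaps are free symmetrically: the DP boundary is initialized
to zero, the optimum is taken over the last row and column, and one
leading and one trailing gap run go unpenalized.  Descriptions of
this mode elsewhere are sometimes asymmetric (free start in one
sequence only); the symmetric convention was chosen because it treats
the two sequences interchangeably, and it is what the exhaustive
enumeration oracle in the tests encodes.

### Determinism

The score is unique but the argmax path is not.  Tie-breaking is
fixed: diagonal over vertical (gap in B) over horizontal (gap in A)
during traceback, and the semi-global end cell is the maximal cell of
the last row/column with ties resolved toward the bottom-right
corner.  Identical inputs therefore always produce identical output.

A useful consequence of exact optimization: the number of
motif-paired columns in the optimal alignment is provably
non-decreasing in α (for optima m₁ at α₁ < α₂ with counts m₁, m₂,
optimality of each gives (α₂−α₁)(m₂−m₁) ≥ 0), so the monotonicity
checked in the tests is a theorem about the implementation being
exact, not an empirical accident.

## Motif annotation

PROSITE pattern syntax is parsed into ordered rules (exact residue,
any, allowed class, excluded class) with repeat counts and optional
terminal anchors.  A rule is informative iff it excludes strictly
more of the 20 amino-acid types than it includes; a class of exactly
10 types is uninformative, and repeats inherit the informativeness of
their base rule (spacing carries no residue information).  By default
only informative positions of a match are annotated; an
all-informative switch annotates whole match spans, useful for very
short patterns.  Matching enumerates every start offset and every
expansion of variable repeats, reporting all (overlapping) matches;
overlapping matches of one pattern annotate the union of their
positions.  Ambiguity codes X/B/Z satisfy only the any-residue rule,
a conservative choice that avoids motif calls on ambiguous residues.

A preservation filter mirrors common benchmark practice: a pattern is
kept for a sequence set when at least a fraction t (default 0.5,
boundary inclusive) of the sequences contain at least one match.

## Progressive strategy

The guide tree is pre-generated from all-vs-all *global* pairwise
scores, shifted per `D = −P + max(P)` (max over off-diagonal entries;
self-scores are unused).  Clustering is hand-rolled O(n³)
agglomerative UPGMA/single/complete with an explicit
lowest-cluster-index tie rule, because deterministic output under
exact ties is a contract here; scipy's implementation is used as an
independent oracle in the tests, not as the implementation.  Node
heights follow the cophenetic convention (height = merge
dissimilarity).

Profile merging reuses the pairwise DP over column pairs.  The column
pair substitution score is the **mean** of S(x, y) over cross-row
pairs with both residues non-gap, and the motif term is α times the
fraction of those pairs sharing an accession.  The mean (rather than
sum) keeps α on the same scale at every merge depth and reduces
exactly to the pairwise scoring for single-sequence profiles.  Pairs
involving a gap contribute to neither numerator nor denominator —
gaps already paid for at earlier merges are not re-penalized — and an
all-gap column pair scores zero.  No sequence weighting is applied.
Columns are only ever interleaved, never reordered, so residue pairs
aligned at an earlier merge stay aligned ("once a gap, always a
gap").

## Scoring

SP score: recovered reference residue pairs over total reference
pairs (reference in the denominator, the benchmark-literature
convention; the measure is therefore directional).  Motif score:
pooled over all columns containing at least one annotated symbol, the
ratio of annotated symbol pairs to all symbol pairs of those columns.
The column pair count uses all rows, so gap symbols act as
non-annotated members of the column — the same convention the α*
counting uses for gaps.  Annotations from multiple patterns are
collapsed first, so a doubly matched position contributes once.  Both
scores are invariant under row reordering and all-gap columns; both
are undefined (None/NA) when their denominator is empty.  The pooled
ratio (sum of numerators over sum of denominators) was chosen over a
mean of per-column ratios; the convention is isolated in
`motif_pair_counts` should anyone want to flip it.

## α* estimation

Per pattern, over reference alignments annotated with that single
pattern (alignments without a match are excluded): P(O) is the pooled
count of both-annotated symbol pairs over all symbol pairs of all
columns, gaps counting as non-match symbols; q_m is annotated
residues over all residues (gap cells are not amino acids and are
excluded); P(E) = q_m², reasonable when motif occurrences are spread
evenly across rows; α* = f·log_b(P(O)/P(E)) with f = b = 2 for
comparability with α and with BLOSUM half-bit scores.  Pair counts
are pooled across alignments (BLOSUM-style) rather than averaged per
alignment; α* is undefined when P(O) = 0.  Perfect conservation gives
the envelope α* = 2·log₂(P(O)/q_m²) with P(O) ≤ q_m, i.e. an upper
bound that decays with q_m — q_m² underestimates the background for
patterns spanning families of very different sizes, and no correction
is attempted.

## Synthetic families

The generator emulates the regime the aligner targets: an ancestor
built of alternating conserved and hypervariable blocks (defaults:
three conserved flanks of 20 around two variable blocks of 25),
descendants drawn by per-position substitution (rates 0.1 conserved /
0.5 variable), and indels confined to the variable blocks (per-site
rate 0.08, geometric lengths of mean 2).  Two N-glycosylation sequon
instances are implanted per variable block at jittered positions;
informative motif positions are mutation-protected, spacer positions
resample until the rule still holds, and indels never cross a motif
span, so every implanted instance survives pattern matching and the
true alignment (with per-column conserved/variable/motif labels) is
known exactly.  One `random.Random(seed)` stream drives everything,
so families are bit-reproducible.

What this does and does not show: the generator has no phylogenetic
structure (star topology from one ancestor), no positional
composition bias, and motif instances occupy homologous ancestor
positions, so passing tests demonstrate that the machinery behaves as
designed in the regime it models — conserved anchors, noisy
motif-bearing regions — not that benchmark scores on curated
databases are reproduced.

## Problem sizes and numerics

The test suite and the acceptance script run at desk scale by design:
exhaustive-enumeration oracles use sequences of length ≤ 7 (every
alignment of such a pair is scored), textbook-aligner and kernel
cross-checks use lengths ≤ 40, and the end-to-end sweep uses 20
families of 10 sequences (~110 residues) at α ∈ {0, 10}.  DP
equality checks against independent implementations are exact on
integer-valued inputs; float comparisons elsewhere use math.isclose.
Traceback re-derives predecessors with a 1e-9 tolerance, which is
exact for the integer matrices plus rational α used in practice.

## Known limitations

No local (Smith–Waterman) mode, PSSM/profile patterns, preprofiles,
iterative refinement, consistency transforms, or sequence weighting;
nucleotide alphabets are out of scope.  Progressive alignment remains
greedy: a misjoin high in the guide tree cannot be undone, and large
α can change the join order itself.  Very large α (≳ 30) degrades
overall quality by letting spurious motif matches override the
substitution signal; α ≈ 10 is a safe default, with 5–20 the useful
range depending on motif conservation.
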