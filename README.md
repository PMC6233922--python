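# mamsa — motif-aware multiple sequence alignment

Short functional motifs — glycosylation sequons, phosphorylation
sites, metal-binding signatures — are often the most strongly
conserved features of a protein family, yet standard aligners
routinely misplace them: the substitution score contributed by a
three- or four-residue motif is drowned out by the surrounding
sequence, especially in hypervariable regions such as the V-loops of
HIV gp120 where the residues around each N-glycosylation sequon churn
freely while the sequons themselves persist.

`mamsa` is a progressive protein multiple-sequence aligner that takes
externally supplied motif patterns (PROSITE pattern syntax) into
account.  It is aimed at anyone aligning families whose functionally
important motifs are known in advance; it is *not* a de novo motif
finder.

## The method

Sequences are annotated by matching PROSITE patterns such as the
sequon `N-{P}-[ST]-{P}`.  Only *informative* pattern positions are
annotated by default: a rule is informative when it excludes more
amino-acid types than it includes, so the `N` and `[ST]` positions of
the sequon count as motif while the `{P}` spacers do not.

Pairwise alignment is dynamic programming over the recurrence

    F[i][j] = max( F[k][j] + g(i-k),   k = 0..i-1
                   F[i][k] + g(j-k),   k = 0..j-1
                   F[i-1][j-1] + S(A_i, B_j) + S_motif(A_i, B_j) )

with `S_motif(x, y) = α` when positions x and y are annotated by the
same motif pattern and 0 otherwise.  `α = 0` recovers conventional
Needleman–Wunsch; larger α biases the optimum toward pairing motif
positions.  Optimized three-state kernels cover linear and affine gap
penalties (defaults: BLOSUM62, gap open −11, extend −1, α = 10); a
cubic reference kernel handles arbitrary gap-length functions.  Both
global and semi-global (free terminal gaps) modes are available.

The multiple alignment is progressive: all-vs-all global pairwise
scores P are shifted into dissimilarities `D_xy = −P_xy + max(P)`, a
guide tree is built by UPGMA (or single/complete linkage), and
profiles are merged in tree order, scoring column pairs by the mean
substitution score over non-gap cross pairs plus α times the fraction
of those pairs sharing a motif.

Alignment quality is measured by the sum-of-pairs (SP) score against
a reference and by the **motif score** — the pooled fraction of
motif-annotated symbol pairs among all symbol pairs in columns
containing at least one motif symbol.  Finally, the package estimates
the motif conservation signal empirically: for a pattern m observed in
a set of reference alignments,

    α* = f · log_b( P(O_motif) / q_m² ),    f = b = 2,

the BLOSUM-style log-odds of motif positions being co-aligned versus
chance, on the same half-bit scale as α so the two are directly
comparable.

## Worked example

Generate a synthetic six-sequence family (conserved flanks,
hypervariable blocks carrying implanted sequons, known true
alignment), then align with and without the motif bonus and score
both against the truth:

```
$ mamsa fixtures --seed 4 --n-sequences 6 --out-dir demo
$ mamsa align demo/family.fasta -p demo/family.patterns.txt --alpha 0  -o demo/aln_a0.afa
$ mamsa align demo/family.fasta -p demo/family.patterns.txt --alpha 10 -o demo/aln_a10.afa
$ mamsa score --test demo/aln_a0.afa  --ref demo/family.ref.afa -p demo/family.patterns.txt
sp      motif   matched_pairs  reference_pairs  motif_pairs  motif_total_pairs
0.923906  0.851852  1457  1577  115  135
$ mamsa score --test demo/aln_a10.afa --ref demo/family.ref.afa -p demo/family.patterns.txt
sp      motif   matched_pairs  reference_pairs  motif_pairs  motif_total_pairs
0.932150  1.000000  1470  1577  120  120
```

At α = 0 the aligner recovers 92.4% of the true residue pairs but
only 85.2% of the motif pairs; at α = 10 every motif column is
recovered (motif score 1.0) while the overall SP score is unchanged
(in fact slightly better, 93.2%).  That is the intended behaviour:
the bonus rescues the motifs without degrading the rest of the
alignment.

The `annotate` subcommand lists raw motif matches as TSV, and
`alphastar` computes the per-pattern (q_m, P(O), P(E), α*) table from
a directory of reference alignments.

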