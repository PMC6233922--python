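"""Alignment quality metrics: sum-of-pairs score and motif score.

The SP score of a test alignment against a reference is the fraction
of residue pairs co-aligned in the reference that the test alignment
recovers (reference pairs in the denominator, the usual benchmark
convention).  The motif score is a pooled ratio over all columns
containing at least one motif-annotated symbol: the number of symbol
pairs in which both symbols are motif-annotated, divided by the total
number of symbol pairs of those columns.  Gap symbols count as
non-annotated members of a column, and a position matched by several
patterns contributes only once (annotations are collapsed).
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import Alignment


@dataclass(frozen=True)
class ScoreReport:
    """SP and motif scores plus the raw pair counts behind them."""

    sp: float | None
    motif: float | None
    matched_pairs: int
    reference_pairs: int
    motif_pairs: int
    motif_total_pairs: int


def _column_of_residue(aln: Alignment) -> dict[tuple[str, int], int]:
    """(row id, ungapped index) -> column index."""
    where: dict[tuple[str, int], int] = {}
    for rid, row in zip(aln.ids, aln.rows):
        k = 0
        for col, c in enumerate(row):
            if c != "-":
                where[(rid, k)] = col
                k += 1
    return where


def sp_pair_counts(test: Alignment, reference: Alignment) -> tuple[int, int]:
    """(recovered pairs, reference pairs) behind the SP score."""
    if sorted(test.ids) != sorted(reference.ids):
        raise ValueError("test and reference alignments hold different ids")
    for rid in test.ids:
        t = test.rows[test.ids.index(rid)].replace("-", "")
        r = reference.rows[reference.ids.index(rid)].replace("-", "")
        if t != r:
            raise ValueError(
                f"row {rid!r} differs between test and reference after degapping"
            )
    test_col = _column_of_residue(test)

    matched = 0
    total = 0
    # enumerate reference co-aligned residue pairs column by column
    ungapped = {rid: 0 for rid in reference.ids}
    for col in range(reference.n_cols):
        present = []
        for rid, row in zip(reference.ids, reference.rows):
            if row[col] != "-":
                present.append((rid, ungapped[rid]))
                ungapped[rid] += 1
        for x in range(len(present)):
            for y in range(x + 1, len(present)):
                total += 1
                if test_col[present[x]] == test_col[present[y]]:
                    matched += 1
    return matched, total


def sp_score(test: Alignment, reference: Alignment) -> float | None:
    """Fraction of reference residue pairs recovered by the test MSA.

    Returns None when the reference contains no co-aligned pair.
    """
    matched, total = sp_pair_counts(test, reference)
    return matched / total if total else None


def motif_pair_counts(alignment: Alignment) -> tuple[int, int]:
    """(annotated pairs, total pairs) over motif-containing columns."""
    if alignment.tracks is None:
        raise ValueError("alignment carries no motif tracks")
    n = alignment.n_rows
    pairs_per_column = n * (n - 1) // 2
    motif_pairs = 0
    total_pairs = 0
    for col in range(alignment.n_cols):
        annotated = sum(1 for tr in alignment.tracks if tr[col])
        if annotated == 0:
            continue
        motif_pairs += annotated * (annotated - 1) // 2
        total_pairs += pairs_per_column
    return motif_pairs, total_pairs


def motif_score(alignment: Alignment) -> float | None:
    """Pooled motif pair ratio; None if no column contains a motif."""
    motif_pairs, total_pairs = motif_pair_counts(alignment)
    return motif_pairs / total_pairs if total_pairs else None


def score_report(test: Alignment, reference: Alignment) -> ScoreReport:
    """SP score of test vs reference plus motif score of the test MSA."""
    matched, total = sp_pair_counts(test, reference)
    if test.tracks is not None:
        mp, mt = motif_pair_counts(test)
    else:
        mp, mt = 0, 0
    return ScoreReport(
        sp=matched / total if total else None,
        motif=mp / mt if mt else None,
        matched_pairs=matched,
        reference_pairs=total,
        motif_pairs=mp,
        motif_total_pairs=mt,
    )
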