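"""Log-odds estimation of the motif conservation signal (alpha*).

For one motif pattern and a set of gapped reference alignments,
alpha* measures how much more often motif-annotated positions are
co-aligned than expected by chance:

    alpha* = f * log_b( P(O_motif) / P(E_motif) )

P(O_motif) is the observed probability that a column symbol pair has
both symbols motif-annotated, pooled over every column of every
included alignment (gaps are non-match symbols).  P(E_motif) is the
background estimate q_m^2, where q_m is the fraction of residues
annotated by the pattern among all residues of the alignments that
contain at least one match.  The defaults f = 2, b = 2 put alpha* on
the BLOSUM half-bit scale so it is directly comparable to the aligner
bonus alpha.

Counting is per pattern, on single-pattern annotation tracks;
alignments without a single match of the pattern are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .motif import PrositePattern, annotate, map_track_through_gaps
from .seqio import Alignment


@dataclass(frozen=True)
class AlphaStarParams:
    """Scaling factor and log base of the log-odds score."""

    f: float = 2.0
    b: float = 2.0

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("scaling factor f must be > 0")
        if self.b <= 1:
            raise ValueError("log base b must be > 1")


@dataclass(frozen=True)
class AlphaStarRecord:
    """Per-pattern counts and the resulting log-odds score.

    ``alpha_star`` is None when no annotated pair is ever co-aligned
    (p_obs = 0), where the log-odds is undefined.
    """

    accession: str
    q_m: float
    p_obs: float
    p_exp: float
    alpha_star: float | None
    n_alignments: int


def _annotated_alignments(alignments: Sequence[Alignment],
                          pattern: PrositePattern,
                          all_informative: bool = False) -> list[Alignment]:
    """Single-pattern tracks per alignment; drop alignments w/o a match."""
    included = []
    for aln in alignments:
        seqs = aln.sequences()
        tracks = annotate(seqs, [pattern], all_informative=all_informative)
        if not any(any(ann for ann in tr) for tr in tracks):
            continue
        gapped = [map_track_through_gaps(tr, row)
                  for tr, row in zip(tracks, aln.rows)]
        included.append(Alignment(list(aln.ids), list(aln.rows), gapped))
    return included


def observed_probability(annotated: Sequence[Alignment]) -> float:
    """Pooled P(O_motif): both-match pairs over all pairs, all columns."""
    if not annotated:
        raise ValueError("no alignments to count")
    match_pairs = 0
    total_pairs = 0
    for aln in annotated:
        if aln.tracks is None:
            raise ValueError("alignment carries no annotation track")
        n = aln.n_rows
        per_col = n * (n - 1) // 2
        total_pairs += per_col * aln.n_cols
        for col in range(aln.n_cols):
            k = sum(1 for tr in aln.tracks if tr[col])
            match_pairs += k * (k - 1) // 2
    if total_pairs == 0:
        raise ValueError("alignments contain no symbol pairs")
    return match_pairs / total_pairs


def compute_qm(annotated: Sequence[Alignment]) -> float:
    """Annotated residues over all residues, pooled (gaps excluded)."""
    if not annotated:
        raise ValueError(
            "no alignment contains a match of the pattern"
        )
    annotated_positions = 0
    residues = 0
    for aln in annotated:
        for row, track in zip(aln.rows, aln.tracks):
            residues += sum(1 for c in row if c != "-")
            annotated_positions += sum(1 for ann in track if ann)
    if residues == 0:
        raise ValueError("alignments contain no residues")
    return annotated_positions / residues


def estimate_alpha_star(alignments: Sequence[Alignment],
                        pattern: PrositePattern,
                        params: AlphaStarParams = AlphaStarParams(),
                        all_informative: bool = False) -> AlphaStarRecord:
    """Eq: alpha* = f * log_b(p_obs / q_m^2) for one pattern."""
    annotated = _annotated_alignments(alignments, pattern, all_informative)
    q_m = compute_qm(annotated)
    p_obs = observed_probability(annotated)
    p_exp = q_m * q_m
    if p_obs > 0 and p_exp > 0:
        alpha_star = params.f * math.log(p_obs / p_exp, params.b)
    else:
        alpha_star = None
    return AlphaStarRecord(pattern.accession, q_m, p_obs, p_exp,
                           alpha_star, len(annotated))


def alpha_star_table(alignments: Sequence[Alignment],
                     patterns: Sequence[PrositePattern],
                     params: AlphaStarParams = AlphaStarParams(),
                     all_informative: bool = False) -> pd.DataFrame:
    """One row per pattern: accession, q_m, p_obs, p_exp, alpha_star.

    Patterns without any match in any alignment are reported with NA
    fields rather than raising.
    """
    rows = []
    for pattern in patterns:
        try:
            rec = estimate_alpha_star(alignments, pattern, params,
                                      all_informative)
        except ValueError:
            rows.append({"accession": pattern.accession, "q_m": None,
                         "p_obs": None, "p_exp": None, "alpha_star": None,
                         "n_alignments": 0})
            continue
        rows.append({"accession": rec.accession, "q_m": rec.q_m,
                     "p_obs": rec.p_obs, "p_exp": rec.p_exp,
                     "alpha_star": rec.alpha_star,
                     "n_alignments": rec.n_alignments})
    return pd.DataFrame(rows, columns=["accession", "q_m", "p_obs",
                                       "p_exp", "alpha_star", "n_alignments"])
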