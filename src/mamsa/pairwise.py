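"""Motif-aware pairwise dynamic-programming alignment.

The substitution score for matching residues A_i and B_j is boosted by
a bonus ``alpha`` whenever both positions are annotated by at least one
common motif pattern; with ``alpha = 0`` the algorithm is an ordinary
Needleman-Wunsch (global) or semi-global aligner.  Two kernels are
provided: an optimized three-state (Gotoh) kernel for linear and
affine gap penalties, and a cubic-time reference kernel for arbitrary
gap-length penalty functions g(l).

Conventions: penalties are non-positive numbers.  Linear gaps cost
g(l) = d*l; affine gaps g(l) = e + d*(l-1), i.e. the open penalty e is
charged for the first gap position and the extension penalty d for each
further one.  Defaults follow common practice for BLOSUM62: open -11,
extend -1, alpha 10.

Traceback ties are broken deterministically: diagonal (match) over
vertical (gap in B) over horizontal (gap in A); the semi-global start
cell is the maximal cell of the last row/column with ties broken
toward the bottom-right corner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .motif import MotifTrack
from .seqio import Alignment, ProteinSequence, SubstitutionMatrix
from .seqio import load_substitution_matrix

NEG_INF = float("-inf")

DEFAULT_GAP_OPEN = -11.0
DEFAULT_GAP_EXTEND = -1.0
DEFAULT_ALPHA = 10.0


@dataclass(frozen=True)
class GapPenalty:
    """Gap cost model: linear, affine, or a general length function."""

    mode: str = "affine"  # linear | affine | general
    d: float = DEFAULT_GAP_EXTEND  # extension penalty (<= 0)
    e: float = DEFAULT_GAP_OPEN  # open penalty (<= 0), affine only
    g: Callable[[int], float] | None = None  # general mode only

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "affine", "general"):
            raise ValueError(f"unknown gap mode {self.mode!r}")
        if self.mode in ("linear", "affine") and self.d > 0:
            raise ValueError("gap extension penalty must be <= 0")
        if self.mode == "affine" and self.e > 0:
            raise ValueError("gap open penalty must be <= 0")
        if self.mode == "general":
            if self.g is None:
                raise ValueError("general mode requires a gap function g")
            if self.g(0) != 0:
                raise ValueError("gap function must satisfy g(0) = 0")

    def cost(self, length: int) -> float:
        """Penalty of one maximal gap run of ``length`` positions."""
        if length == 0:
            return 0.0
        if self.mode == "linear":
            return self.d * length
        if self.mode == "affine":
            return self.e + self.d * (length - 1)
        return self.g(length)

    @property
    def open_(self) -> float:
        """Cost of the first position of a gap run."""
        return self.d if self.mode == "linear" else self.e


@dataclass(frozen=True)
class AlignParams:
    """Everything the aligner needs besides the two sequences."""

    matrix: SubstitutionMatrix
    gaps: GapPenalty = field(default_factory=GapPenalty)
    alpha: float = DEFAULT_ALPHA
    mode: str = "global"  # global | semiglobal

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.mode not in ("global", "semiglobal"):
            raise ValueError(f"unknown alignment mode {self.mode!r}")


def default_params(alpha: float = DEFAULT_ALPHA, mode: str = "global",
                   matrix: str = "blosum62") -> AlignParams:
    return AlignParams(load_substitution_matrix(matrix),
                       GapPenalty("affine", DEFAULT_GAP_EXTEND, DEFAULT_GAP_OPEN),
                       alpha, mode)


@dataclass
class PairwiseResult:
    """Score plus the column operations of one optimal alignment.

    Operations are ``("M", i, j)`` matching A_i to B_j, ``("GB", i)``
    placing A_i against a gap in B, and ``("GA", j)`` placing B_j
    against a gap in A (0-based ungapped indices).
    """

    score: float
    path: list[tuple]
    seq_a: ProteinSequence
    seq_b: ProteinSequence
    track_a: MotifTrack | None = None
    track_b: MotifTrack | None = None

    def as_alignment(self) -> Alignment:
        row_a = []
        row_b = []
        for op in self.path:
            if op[0] == "M":
                row_a.append(self.seq_a.residues[op[1]])
                row_b.append(self.seq_b.residues[op[2]])
            elif op[0] == "GB":
                row_a.append(self.seq_a.residues[op[1]])
                row_b.append("-")
            else:
                row_a.append("-")
                row_b.append(self.seq_b.residues[op[1]])
        aln = Alignment([self.seq_a.id, self.seq_b.id],
                        ["".join(row_a), "".join(row_b)])
        if self.track_a is not None and self.track_b is not None:
            from .motif import map_track_through_gaps

            aln.tracks = [map_track_through_gaps(self.track_a, aln.rows[0]),
                          map_track_through_gaps(self.track_b, aln.rows[1])]
        return aln

    def motif_pair_columns(self) -> int:
        """Number of matched columns whose two positions share a motif."""
        if self.track_a is None or self.track_b is None:
            return 0
        n = 0
        for op in self.path:
            if op[0] == "M" and self.track_a[op[1]] & self.track_b[op[2]]:
                n += 1
        return n


def motif_bonus(ann_a: frozenset, ann_b: frozenset, alpha: float) -> float:
    """``alpha`` when the two annotation sets share an accession, else 0."""
    return alpha if ann_a & ann_b else 0.0


def _substitution_scores(seq_a: ProteinSequence, seq_b: ProteinSequence,
                         track_a: MotifTrack | None,
                         track_b: MotifTrack | None,
                         params: AlignParams) -> np.ndarray:
    """Dense (len_a x len_b) table S(A_i,B_j) + S_motif(A_i,B_j)."""
    matrix = params.matrix
    sub = matrix.scores[np.ix_(matrix.encode(seq_a.residues),
                               matrix.encode(seq_b.residues))].astype(float)
    if params.alpha and track_a is not None and track_b is not None:
        ann_a = [i for i, s in enumerate(track_a) if s]
        ann_b = [j for j, s in enumerate(track_b) if s]
        for i in ann_a:
            sa = track_a[i]
            for j in ann_b:
                if sa & track_b[j]:
                    sub[i, j] += params.alpha
    return sub


def _affine_dp(sub: Sequence[Sequence[float]], n: int, m: int,
               gaps: GapPenalty, mode: str) -> tuple[float, list[tuple]]:
    """Three-state DP over a precomputed score table.

    States: M (match ending at (i,j)), V (gap in B: A_i against gap),
    H (gap in A: B_j against gap).  Returns the optimal score and the
    op path as ("M"|"GB"|"GA", i, j) steps in forward order, where i/j
    are the consumed 0-based indices.
    """
    open_ = gaps.open_
    ext = gaps.d
    free_ends = mode == "semiglobal"

    # score layers, row-major (n+1) x (m+1)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    V = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    H = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        V[i][0] = 0.0 if free_ends else open_ + ext * (i - 1)
    for j in range(1, m + 1):
        H[0][j] = 0.0 if free_ends else open_ + ext * (j - 1)

    for i in range(1, n + 1):
        Mi, Vi, Hi = M[i], V[i], H[i]
        Mp, Vp, Hp = M[i - 1], V[i - 1], H[i - 1]
        srow = sub[i - 1]
        for j in range(1, m + 1):
            s = srow[j - 1]
            jp = j - 1
            best = Mp[jp]
            if Vp[jp] > best:
                best = Vp[jp]
            if Hp[jp] > best:
                best = Hp[jp]
            Mi[j] = best + s
            # V: A_i against gap in B (vertical step)
            v = Mp[j] + open_
            if Hp[j] + open_ > v:
                v = Hp[j] + open_
            if Vp[j] + ext > v:
                v = Vp[j] + ext
            Vi[j] = v
            # H: B_j against gap in A (horizontal step)
            h = Mi[jp] + open_
            if Vi[jp] + open_ > h:
                h = Vi[jp] + open_
            if Hi[jp] + ext > h:
                h = Hi[jp] + ext
            Hi[j] = h

    def cell_best(i: int, j: int) -> float:
        return max(M[i][j], V[i][j], H[i][j])

    # pick the end cell
    if free_ends:
        end_i, end_j, end_score = n, m, cell_best(n, m)
        # ties toward the bottom-right: scan away from the corner and
        # replace only on a strictly better score
        for j in range(m - 1, -1, -1):
            sc = cell_best(n, j)
            if sc > end_score:
                end_i, end_j, end_score = n, j, sc
        for i in range(n - 1, -1, -1):
            sc = cell_best(i, m)
            if sc > end_score:
                end_i, end_j, end_score = i, m, sc
    else:
        end_i, end_j, end_score = n, m, cell_best(n, m)

    # traceback with precedence M > V > H; once a row/column boundary is
    # reached the rest of the path is forced (appended after the loop)
    ops: list[tuple] = []
    for i in range(n - 1, end_i - 1, -1):
        ops.append(("GB", i))
    for j in range(m - 1, end_j - 1, -1):
        ops.append(("GA", j))
    i, j = end_i, end_j
    tol = 1e-9
    state = "M"
    for st, layer in (("M", M), ("V", V), ("H", H)):
        if layer[i][j] >= end_score - tol:
            state = st
            break
    while i > 0 and j > 0:
        if state == "M":
            target = M[i][j] - sub[i - 1][j - 1]
            ops.append(("M", i - 1, j - 1))
            i, j = i - 1, j - 1
            if abs(M[i][j] - target) <= tol:
                state = "M"
            elif abs(V[i][j] - target) <= tol:
                state = "V"
            else:
                state = "H"
        elif state == "V":
            target = V[i][j]
            ops.append(("GB", i - 1))
            i -= 1
            if abs(M[i][j] + open_ - target) <= tol:
                state = "M"
            elif abs(V[i][j] + ext - target) <= tol:
                state = "V"
            else:
                state = "H"
        else:
            target = H[i][j]
            ops.append(("GA", j - 1))
            j -= 1
            if abs(M[i][j] + open_ - target) <= tol:
                state = "M"
            elif abs(H[i][j] + ext - target) <= tol:
                state = "H"
            else:
                state = "V"
    for k in range(i - 1, -1, -1):
        ops.append(("GB", k))
    for k in range(j - 1, -1, -1):
        ops.append(("GA", k))
    ops.reverse()
    return end_score, ops


def align_pair(seq_a: ProteinSequence, seq_b: ProteinSequence,
               params: AlignParams,
               track_a: MotifTrack | None = None,
               track_b: MotifTrack | None = None) -> PairwiseResult:
    """Optimal motif-aware alignment with the linear/affine kernel.

    Global mode anchors both termini; semiglobal mode makes terminal
    gaps in either sequence free.
    """
    if params.gaps.mode not in ("linear", "affine"):
        raise ValueError("align_pair requires a linear or affine gap model")
    n, m = len(seq_a), len(seq_b)
    if n == 0 or m == 0:
        return _empty_result(seq_a, seq_b, params, track_a, track_b)
    sub = _substitution_scores(seq_a, seq_b, track_a, track_b, params).tolist()
    gaps = params.gaps
    if gaps.mode == "linear":
        gaps = GapPenalty("affine", gaps.d, gaps.d)
    score, ops = _affine_dp(sub, n, m, gaps, params.mode)
    return PairwiseResult(score, ops, seq_a, seq_b, track_a, track_b)


def _empty_result(seq_a, seq_b, params, track_a, track_b) -> PairwiseResult:
    n, m = len(seq_a), len(seq_b)
    ops: list[tuple] = [("GB", i) for i in range(n)]
    ops += [("GA", j) for j in range(m)]
    if params.mode == "semiglobal":
        score = 0.0
    else:
        score = params.gaps.cost(n) + params.gaps.cost(m)
    return PairwiseResult(score, ops, seq_a, seq_b, track_a, track_b)


def align_pair_general(seq_a: ProteinSequence, seq_b: ProteinSequence,
                       params: AlignParams,
                       track_a: MotifTrack | None = None,
                       track_b: MotifTrack | None = None) -> PairwiseResult:
    """Reference kernel for arbitrary gap functions (cubic time).

    Directly maximizes the recurrence
    ``F[i][j] = max(F[k][j] + g(i-k), F[i][k] + g(j-k),
    F[i-1][j-1] + S + S_motif)`` and therefore agrees with
    :func:`align_pair` for linear and affine g (with open <= extend it
    never pays to split a gap run).
    """
    gaps = params.gaps
    g = gaps.cost
    if g(0) != 0:
        raise ValueError("gap function must satisfy g(0) = 0")
    n, m = len(seq_a), len(seq_b)
    if n == 0 or m == 0:
        return _empty_result(seq_a, seq_b, params, track_a, track_b)
    sub = _substitution_scores(seq_a, seq_b, track_a, track_b, params).tolist()
    free_ends = params.mode == "semiglobal"

    F = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    F[0][0] = 0.0
    for i in range(1, n + 1):
        F[i][0] = 0.0 if free_ends else g(i)
    for j in range(1, m + 1):
        F[0][j] = 0.0 if free_ends else g(j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = F[i - 1][j - 1] + sub[i - 1][j - 1]
            for k in range(i):
                v = F[k][j] + g(i - k)
                if v > best:
                    best = v
            for k in range(j):
                v = F[i][k] + g(j - k)
                if v > best:
                    best = v
            F[i][j] = best

    if free_ends:
        end_i, end_j = n, m
        end_score = F[n][m]
        for j in range(m - 1, -1, -1):
            if F[n][j] > end_score:
                end_i, end_j, end_score = n, j, F[n][j]
        for i in range(n - 1, -1, -1):
            if F[i][m] > end_score:
                end_i, end_j, end_score = i, m, F[i][m]
    else:
        end_i, end_j, end_score = n, m, F[n][m]

    tol = 1e-9
    ops: list[tuple] = []
    for i in range(n - 1, end_i - 1, -1):
        ops.append(("GB", i))
    for j in range(m - 1, end_j - 1, -1):
        ops.append(("GA", j))
    i, j = end_i, end_j
    while i > 0 or j > 0:
        if free_ends and (i == 0 or j == 0):
            break
        cur = F[i][j]
        if (i > 0 and j > 0
                and abs(F[i - 1][j - 1] + sub[i - 1][j - 1] - cur) <= tol):
            ops.append(("M", i - 1, j - 1))
            i, j = i - 1, j - 1
            continue
        done = False
        for k in range(i - 1, -1, -1):
            if abs(F[k][j] + g(i - k) - cur) <= tol:
                for p in range(i - 1, k - 1, -1):
                    ops.append(("GB", p))
                i = k
                done = True
                break
        if done:
            continue
        for k in range(j - 1, -1, -1):
            if abs(F[i][k] + g(j - k) - cur) <= tol:
                for p in range(j - 1, k - 1, -1):
                    ops.append(("GA", p))
                j = k
                done = True
                break
        if not done:  # pragma: no cover - defensive
            raise RuntimeError("traceback failed in general kernel")
    for k in range(i - 1, -1, -1):
        ops.append(("GB", k))
    for k in range(j - 1, -1, -1):
        ops.append(("GA", k))
    ops.reverse()
    return PairwiseResult(end_score, ops, seq_a, seq_b, track_a, track_b)


def score_path(result: PairwiseResult, params: AlignParams) -> float:
    """Re-score an alignment path from scratch (maximal gap runs).

    Terminal gap runs are free in semiglobal mode.  Used to check the
    internal consistency of DP score and traceback.
    """
    matrix = params.matrix
    a, b = result.seq_a.residues, result.seq_b.residues
    ta, tb = result.track_a, result.track_b
    total = 0.0
    # blocks of consecutive ops of one type; gap runs are per sequence
    blocks: list[tuple[str, int]] = []
    for op in result.path:
        if blocks and blocks[-1][0] == op[0]:
            blocks[-1] = (op[0], blocks[-1][1] + 1)
        else:
            blocks.append((op[0], 1))
    for k, (kind, length) in enumerate(blocks):
        if kind == "M":
            continue
        terminal = k == 0 or k == len(blocks) - 1
        if params.mode == "semiglobal" and terminal:
            continue
        total += params.gaps.cost(length)
    for op in result.path:
        if op[0] == "M":
            i, j = op[1], op[2]
            total += matrix.score(a[i], b[j])
            if ta is not None and tb is not None:
                total += motif_bonus(ta[i], tb[j], params.alpha)
    return total
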