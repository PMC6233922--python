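"""Progressive multiple alignment over a clustered guide tree.

All-vs-all global pairwise scores P are shifted into a dissimilarity
matrix D = -P + max(P), so the best-scoring pair gets distance zero.
A guide tree is built from D by agglomerative clustering (UPGMA by
default; single and complete linkage available) and the MSA grows by
merging profiles in post-order of that tree.

Profile merging runs the same gap machinery as the pairwise aligner
over column pairs.  The substitution score of a column pair is the
mean of S(x, y) over all cross-row residue pairs in which both
residues are non-gap, and the motif term is alpha times the fraction
of those pairs sharing a pattern accession; this reduces exactly to
the pairwise scoring when both profiles hold single sequences, and
keeps alpha on the same scale at every merge depth.  Gap-only cross
pairs contribute nothing, and an all-gap column pair scores zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motif import MotifTrack, map_track_through_gaps
from .pairwise import AlignParams, _affine_dp, align_pair, GapPenalty
from .seqio import Alignment, ProteinSequence


@dataclass
class GuideTree:
    """A rooted binary guide tree node.

    Leaves carry a sequence ``index``; internal nodes carry the merge
    ``height`` (the dissimilarity at which the two children joined).
    """

    index: int | None = None
    left: "GuideTree | None" = None
    right: "GuideTree | None" = None
    height: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.index is not None

    def leaves(self) -> list[int]:
        if self.is_leaf:
            return [self.index]
        return self.left.leaves() + self.right.leaves()

    def to_newick(self, names: list[str] | None = None) -> str:
        def label(node: GuideTree) -> str:
            if names is None:
                return f"seq{node.index}"
            return names[node.index]

        def render(node: GuideTree, parent_height: float) -> str:
            branch = max(parent_height - node.height, 0.0)
            if node.is_leaf:
                return f"{label(node)}:{branch:.6g}"
            inner = ",".join(
                render(c, node.height) for c in (node.left, node.right)
            )
            return f"({inner}):{branch:.6g}"

        inner = ",".join(
            render(c, self.height) for c in (self.left, self.right)
        )
        return f"({inner});"

    def cophenetic(self, n: int) -> np.ndarray:
        """n x n matrix of pairwise merge heights (for tree comparison)."""
        out = np.zeros((n, n))

        def walk(node: GuideTree) -> list[int]:
            if node.is_leaf:
                return [node.index]
            lhs, rhs = walk(node.left), walk(node.right)
            for a in lhs:
                for b in rhs:
                    out[a, b] = out[b, a] = node.height
            return lhs + rhs

        walk(self)
        return out


def pairwise_score_matrix(sequences: list[ProteinSequence],
                          params: AlignParams,
                          tracks: list[MotifTrack] | None = None
                          ) -> np.ndarray:
    """Symmetric matrix of global pairwise alignment scores."""
    n = len(sequences)
    if n < 2:
        raise ValueError("need at least two sequences")
    global_params = AlignParams(params.matrix, params.gaps, params.alpha,
                                "global")
    P = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = align_pair(
                sequences[i], sequences[j], global_params,
                tracks[i] if tracks else None,
                tracks[j] if tracks else None,
            )
            P[i, j] = P[j, i] = res.score
    return P


def to_dissimilarity(P: np.ndarray) -> np.ndarray:
    """Shift scores so the best pair is at distance 0: D = -P + max(P).

    The worst pair lands at -min(P) + max(P).  Only off-diagonal
    entries are meaningful; the diagonal is set to 0.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    off = ~np.eye(n, dtype=bool)
    D = -P + P[off].max()
    np.fill_diagonal(D, 0.0)
    return D


def build_guide_tree(D: np.ndarray, linkage: str = "upgma") -> GuideTree:
    """Agglomerative clustering of a dissimilarity matrix.

    Node heights are the dissimilarity at which clusters merge (the
    cophenetic convention).  Exact ties merge the lexicographically
    smallest cluster-index pair, which makes the tree deterministic.
    """
    if linkage not in ("upgma", "single", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n < 2:
        raise ValueError("dissimilarity matrix must be square, n >= 2")
    if not np.allclose(D, D.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("dissimilarity matrix must be nonnegative")

    nodes: dict[int, GuideTree] = {i: GuideTree(index=i) for i in range(n)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    active = list(range(n))
    while len(active) > 1:
        best = min(
            ((dist[(a, b)], a, b)
             for ai, a in enumerate(active) for b in active[ai + 1:]),
        )
        d_merge, a, b = best
        node = GuideTree(left=nodes[a], right=nodes[b], height=d_merge)
        nodes[next_id] = node
        sizes[next_id] = sizes[a] + sizes[b]
        for c in active:
            if c in (a, b):
                continue
            da = dist[tuple(sorted((a, c)))]
            db = dist[tuple(sorted((b, c)))]
            if linkage == "single":
                dn = min(da, db)
            elif linkage == "complete":
                dn = max(da, db)
            else:
                dn = (sizes[a] * da + sizes[b] * db) / (sizes[a] + sizes[b])
            dist[(c, next_id)] = dn
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return nodes[next_id - 1]


def _column_counts(aln: Alignment, matrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-column residue count matrix and non-gap counts."""
    L = len(matrix.alphabet)
    C = np.zeros((aln.n_cols, L))
    for row in aln.rows:
        for col, c in enumerate(row):
            if c != "-":
                C[col, matrix._index[c]] += 1
    return C, C.sum(axis=1)


def _column_masks(aln: Alignment, acc_bits: dict[str, int]) -> list[list[int]]:
    """Per column, the nonzero accession bitmasks of its annotated rows."""
    masks: list[list[int]] = [[] for _ in range(aln.n_cols)]
    if aln.tracks is None:
        return masks
    for track in aln.tracks:
        for col, ann in enumerate(track):
            if ann:
                m = 0
                for acc in ann:
                    m |= acc_bits[acc]
                masks[col].append(m)
    return masks


def _profile_score_table(a: Alignment, b: Alignment,
                         params: AlignParams) -> np.ndarray:
    matrix = params.matrix
    CA, ngA = _column_counts(a, matrix)
    CB, ngB = _column_counts(b, matrix)
    denom = np.outer(ngA, ngB)
    table = CA @ matrix.scores @ CB.T
    np.divide(table, denom, out=table, where=denom > 0)
    table[denom == 0] = 0.0

    if params.alpha and a.tracks is not None and b.tracks is not None:
        accs = sorted(
            {acc for tr in (a.tracks + b.tracks) for ann in tr for acc in ann}
        )
        acc_bits = {acc: 1 << k for k, acc in enumerate(accs)}
        masks_a = _column_masks(a, acc_bits)
        masks_b = _column_masks(b, acc_bits)
        cols_a = [i for i, mm in enumerate(masks_a) if mm]
        cols_b = [j for j, mm in enumerate(masks_b) if mm]
        for i in cols_a:
            ma = masks_a[i]
            for j in cols_b:
                shared = sum(1 for x in ma for y in masks_b[j] if x & y)
                if shared:
                    table[i, j] += params.alpha * shared / denom[i, j]
    return table


def align_profiles(a: Alignment, b: Alignment,
                   params: AlignParams) -> Alignment:
    """Merge two profiles by global or semiglobal block alignment.

    Columns of each input profile are only ever interleaved with new
    all-gap columns; member alignments are preserved as sub-alignments.
    """
    if not a.rows or not b.rows:
        raise ValueError("cannot align an empty profile")
    if params.gaps.mode not in ("linear", "affine"):
        raise ValueError("profile merging requires a linear or affine gap model")
    table = _profile_score_table(a, b, params).tolist()
    gaps = params.gaps
    if gaps.mode == "linear":
        gaps = GapPenalty("affine", gaps.d, gaps.d)
    _, ops = _affine_dp(table, a.n_cols, b.n_cols, gaps, params.mode)

    na, nb = a.n_rows, b.n_rows
    rows = [[] for _ in range(na + nb)]
    has_tracks = a.tracks is not None and b.tracks is not None
    tracks: list[list[frozenset]] = [[] for _ in range(na + nb)]
    empty = frozenset()
    for op in ops:
        if op[0] == "M":
            i, j = op[1], op[2]
            for r in range(na):
                rows[r].append(a.rows[r][i])
            for r in range(nb):
                rows[na + r].append(b.rows[r][j])
            if has_tracks:
                for r in range(na):
                    tracks[r].append(a.tracks[r][i])
                for r in range(nb):
                    tracks[na + r].append(b.tracks[r][j])
        elif op[0] == "GB":  # consume a column of A against gaps in B
            i = op[1]
            for r in range(na):
                rows[r].append(a.rows[r][i])
            for r in range(nb):
                rows[na + r].append("-")
            if has_tracks:
                for r in range(na):
                    tracks[r].append(a.tracks[r][i])
                for r in range(nb):
                    tracks[na + r].append(empty)
        else:  # GA: consume a column of B against gaps in A
            j = op[1]
            for r in range(na):
                rows[r].append("-")
            for r in range(nb):
                rows[na + r].append(b.rows[r][j])
            if has_tracks:
                for r in range(na):
                    tracks[r].append(empty)
                for r in range(nb):
                    tracks[na + r].append(b.tracks[r][j])
    merged = Alignment(
        a.ids + b.ids,
        ["".join(r) for r in rows],
        [tuple(t) for t in tracks] if has_tracks else None,
    )
    return merged


def progressive_align(sequences: list[ProteinSequence],
                      params: AlignParams,
                      tracks: list[MotifTrack] | None = None,
                      linkage: str = "upgma",
                      tree: GuideTree | None = None) -> Alignment:
    """Full progressive MSA: scores -> dissimilarities -> tree -> merges.

    Rows of the result follow the input sequence order; motif tracks,
    when given, travel through every merge in gapped coordinates.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    if tree is None:
        P = pairwise_score_matrix(sequences, params, tracks)
        tree = build_guide_tree(to_dissimilarity(P), linkage)

    def leaf_profile(i: int) -> Alignment:
        seq = sequences[i]
        tr = None
        if tracks is not None:
            tr = [map_track_through_gaps(tracks[i], seq.residues)]
        return Alignment([seq.id], [seq.residues], tr)

    def merge(node: GuideTree) -> Alignment:
        if node.is_leaf:
            return leaf_profile(node.index)
        return align_profiles(merge(node.left), merge(node.right), params)

    result = merge(tree)
    return result.reordered([s.id for s in sequences])


def guide_tree(sequences: list[ProteinSequence], params: AlignParams,
               tracks: list[MotifTrack] | None = None,
               linkage: str = "upgma") -> GuideTree:
    """Convenience wrapper: tree from raw sequences."""
    P = pairwise_score_matrix(sequences, params, tracks)
    return build_guide_tree(to_dissimilarity(P), linkage)
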