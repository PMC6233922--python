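"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the package's dynamic-programming
and backtracking code paths: alignments are scored by exhaustive
enumeration of op sequences, motif matching goes through Python's
``re`` engine on explicitly expanded patterns, and clustering is
cross-checked against scipy.
"""

from __future__ import annotations

import itertools
import re

NEG_INF = float("-inf")


# ---------------------------------------------------------------- alignment

def enumerate_paths(n: int, m: int):
    """Yield every alignment of an n-residue vs m-residue sequence as a
    list of ("M", i, j) / ("GB", i) / ("GA", j) ops."""
    acc: list[tuple] = []

    def gen(i: int, j: int):
        if i == n and j == m:
            yield list(acc)
            return
        if i < n and j < m:
            acc.append(("M", i, j))
            yield from gen(i + 1, j + 1)
            acc.pop()
        if i < n:
            acc.append(("GB", i))
            yield from gen(i + 1, j)
            acc.pop()
        if j < m:
            acc.append(("GA", j))
            yield from gen(i, j + 1)
            acc.pop()

    yield from gen(0, 0)


def score_ops(ops, sub, gap_cost, mode: str) -> float:
    """Score one op sequence.

    ``sub[i][j]`` is the (motif-boosted) substitution score,
    ``gap_cost(l)`` the penalty of one maximal same-sequence gap run.
    In semiglobal mode the first and last blocks are free when they are
    gap blocks.
    """
    blocks: list[tuple[str, int]] = []
    for op in ops:
        if blocks and blocks[-1][0] == op[0]:
            blocks[-1] = (op[0], blocks[-1][1] + 1)
        else:
            blocks.append((op[0], 1))
    total = 0.0
    for op in ops:
        if op[0] == "M":
            total += sub[op[1]][op[2]]
    for k, (kind, length) in enumerate(blocks):
        if kind == "M":
            continue
        if mode == "semiglobal" and (k == 0 or k == len(blocks) - 1):
            continue
        total += gap_cost(length)
    return total


def best_alignment_score(n: int, m: int, sub, gap_cost, mode: str) -> float:
    """Maximum score over every alignment, by exhaustive enumeration."""
    best = NEG_INF
    for ops in enumerate_paths(n, m):
        s = score_ops(ops, sub, gap_cost, mode)
        if s > best:
            best = s
    return best


def substitution_table(seq_a: str, seq_b: str, matrix, alpha: float = 0.0,
                       track_a=None, track_b=None):
    """Plain lookup table S + motif bonus, built without the package's
    vectorized helper."""
    table = []
    for i, x in enumerate(seq_a):
        row = []
        for j, y in enumerate(seq_b):
            s = matrix.score(x, y)
            if (alpha and track_a is not None and track_b is not None
                    and set(track_a[i]) & set(track_b[j])):
                s += alpha
            row.append(s)
        table.append(row)
    return table


# ------------------------------------------------------------------- motifs

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _rule_regex(rule) -> str:
    if rule.kind == "any":
        return "."  # ambiguity codes allowed only here
    if rule.kind == "exact":
        return next(iter(rule.residue_set))
    if rule.kind == "one_of":
        return "[" + "".join(sorted(rule.residue_set)) + "]"
    allowed = sorted(set(_AA) - rule.residue_set)
    return "[" + "".join(allowed) + "]"


def regex_matches(pattern, sequence) -> list[tuple[int, int, tuple[bool, ...]]]:
    """All (start, end, informative_mask) matches, via the re module.

    Every combination of repeat counts is expanded into one fixed-length
    regular expression and tried at every offset.
    """
    seq = sequence.residues
    n = len(seq)
    rules = pattern.rules
    flags = pattern.informative
    count_ranges = [range(r.min_repeat, r.max_repeat + 1) for r in rules]
    found = set()
    for counts in itertools.product(*count_ranges):
        regex = re.compile("".join(
            _rule_regex(r) * c for r, c in zip(rules, counts)
        ))
        mask = tuple(
            f for r, c, f in zip(rules, counts, flags) for _ in range(c)
        )
        length = len(mask)
        starts = [0] if pattern.anchored_start else range(n + 1)
        for start in starts:
            if start + length > n:
                continue
            if pattern.anchored_end and start + length != n:
                continue
            if regex.fullmatch(seq, start, start + length):
                found.add((start, start + length, mask))
    return sorted(found)


# --------------------------------------------------------------- clustering

def scipy_cophenetic(D, linkage_name: str):
    """Cophenetic distance matrix from scipy's agglomerative clustering."""
    from scipy.cluster.hierarchy import cophenet, linkage
    from scipy.spatial.distance import squareform

    method = {"upgma": "average", "single": "single",
              "complete": "complete"}[linkage_name]
    Z = linkage(squareform(D, checks=False), method=method)
    return squareform(cophenet(Z))


# ------------------------------------------------------------------ scoring

def pair_set(alignment):
    """Set of co-aligned residue pairs {((id, i), (id, j)), ...}."""
    pairs = set()
    counters = {rid: 0 for rid in alignment.ids}
    for col in range(alignment.n_cols):
        present = []
        for rid, row in zip(alignment.ids, alignment.rows):
            if row[col] != "-":
                present.append((rid, counters[rid]))
                counters[rid] += 1
        for a, b in itertools.combinations(sorted(present), 2):
            pairs.add((a, b))
    return pairs
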