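"""PROSITE pattern parsing, motif matching and annotation tracks.

A PROSITE pattern such as ``N-{P}-[ST]-{P}`` is an ordered list of
rules: an exact residue, ``x`` (any residue), ``[..]`` (allowed set),
or ``{..}`` (excluded set), each optionally repeated ``(n)`` or
``(n,m)``, with optional ``<``/``>`` anchors at the termini.  A rule is
*informative* when it excludes strictly more amino-acid types than it
includes; by default only informative positions of a match are
annotated as motif, because uninformative rules (e.g. ``x(8)``) merely
encode spacing.

Matching enumerates every start offset and, for variable repeats,
every expansion length, so overlapping matches are all reported.
Ambiguity codes X/B/Z satisfy only the any-residue rule: exact,
``[..]`` and ``{..}`` rules all reject them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .seqio import AMINO_ACIDS, ProteinSequence

_ALPHABET = frozenset(AMINO_ACIDS)


class PatternSyntaxError(ValueError):
    """Malformed PROSITE pattern text."""


@dataclass(frozen=True)
class PatternRule:
    """One element of a PROSITE pattern.

    ``residue_set`` holds the *included* residues for ``exact``/``any``/
    ``one_of`` rules and the *excluded* residues for ``none_of``.
    """

    kind: str  # exact | any | one_of | none_of
    residue_set: frozenset
    min_repeat: int = 1
    max_repeat: int = 1
    anchored_start: bool = False
    anchored_end: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("exact", "any", "one_of", "none_of"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.kind == "exact" and len(self.residue_set) != 1:
            raise ValueError("exact rule must hold exactly one residue")
        if self.kind == "any" and self.residue_set != _ALPHABET:
            raise ValueError("any rule must include the full alphabet")
        if self.kind == "none_of" and not self.residue_set:
            raise ValueError("none_of rule with empty excluded set")
        if not (1 <= self.min_repeat <= self.max_repeat):
            raise ValueError("invalid repeat range")

    def accepts(self, residue: str) -> bool:
        """Whether one residue satisfies this rule.

        Ambiguity codes (X/B/Z) only ever satisfy the any-residue rule.
        """
        if self.kind == "any":
            return True
        if residue not in _ALPHABET:
            return False
        if self.kind == "none_of":
            return residue not in self.residue_set
        return residue in self.residue_set

    @property
    def included_count(self) -> int:
        if self.kind == "none_of":
            return 20 - len(self.residue_set)
        return len(self.residue_set)


def rule_is_informative(rule: PatternRule) -> bool:
    """True iff the rule excludes strictly more residue types than it
    includes, over the 20-letter alphabet.

    ``{P}`` includes 19 types and is uninformative; ``[AW]`` includes 2
    and is informative; a class of exactly 10 types is uninformative.
    """
    included = rule.included_count
    return (20 - included) > included


@dataclass(frozen=True)
class PrositePattern:
    """A parsed PROSITE pattern with per-rule informativeness flags."""

    accession: str
    rules: tuple[PatternRule, ...]
    informative: tuple[bool, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("pattern must contain at least one rule")
        if not self.informative:
            object.__setattr__(
                self, "informative",
                tuple(rule_is_informative(r) for r in self.rules),
            )
        if len(self.informative) != len(self.rules):
            raise ValueError("informative flags do not match rules")

    @property
    def anchored_start(self) -> bool:
        return self.rules[0].anchored_start

    @property
    def anchored_end(self) -> bool:
        return self.rules[-1].anchored_end


@dataclass(frozen=True)
class MotifMatch:
    """One pattern match on one sequence.

    ``start``/``end`` are 0-based half-open ungapped coordinates;
    ``informative_mask`` flags, per matched position, whether the rule
    that consumed it is informative.
    """

    sequence_id: str
    start: int
    end: int
    accession: str
    informative_mask: tuple[bool, ...]

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.informative_mask):
            raise ValueError("mask length does not match match span")


_ELEMENT_RE = re.compile(
    r"(?P<start><)?"
    r"(?:(?P<exact>[A-Za-z])|\[(?P<one_of>[A-Za-z]*)\]|\{(?P<none_of>[A-Za-z]*)\})"
    r"(?:\((?P<rmin>\d+)(?:,(?P<rmax>\d+))?\))?"
    r"(?P<end>>)?"
)


def parse_pattern(text: str, accession: str = "PAT") -> PrositePattern:
    """Parse PROSITE pattern syntax into an ordered rule list.

    Accepts residue letters, ``x``, ``[..]``, ``{..}``, ``-`` separators,
    repeats ``(n)`` / ``(n,m)``, terminal ``<`` / ``>`` anchors and an
    optional trailing ``.`` as used in PROSITE flatfiles.
    """
    stripped = text.strip().rstrip(".")
    if not stripped:
        raise PatternSyntaxError("empty pattern")
    rules: list[PatternRule] = []
    for pos, element in enumerate(stripped.split("-")):
        element = element.strip()
        if not element:
            raise PatternSyntaxError(f"empty element at position {pos + 1}")
        m = _ELEMENT_RE.fullmatch(element)
        if m is None:
            raise PatternSyntaxError(
                f"malformed element {element!r} at position {pos + 1}"
            )
        if m.group("exact") is not None:
            letter = m.group("exact").upper()
            if letter == "X":
                kind, rset = "any", _ALPHABET
            elif letter in _ALPHABET:
                kind, rset = "exact", frozenset(letter)
            else:
                raise PatternSyntaxError(
                    f"unknown residue {letter!r} at position {pos + 1}"
                )
        elif m.group("one_of") is not None:
            letters = frozenset(m.group("one_of").upper())
            if not letters:
                raise PatternSyntaxError(f"empty class [] at position {pos + 1}")
            if not letters <= _ALPHABET:
                raise PatternSyntaxError(
                    f"non-residue in class at position {pos + 1}"
                )
            kind, rset = "one_of", letters
        else:
            letters = frozenset(m.group("none_of").upper())
            if not letters:
                raise PatternSyntaxError(f"empty class {{}} at position {pos + 1}")
            if not letters <= _ALPHABET:
                raise PatternSyntaxError(
                    f"non-residue in class at position {pos + 1}"
                )
            kind, rset = "none_of", letters
        rmin = int(m.group("rmin")) if m.group("rmin") else 1
        rmax = int(m.group("rmax")) if m.group("rmax") else rmin
        if rmin < 1 or rmax < rmin:
            raise PatternSyntaxError(
                f"invalid repeat ({rmin},{rmax}) at position {pos + 1}"
            )
        anchored_start = m.group("start") is not None
        anchored_end = m.group("end") is not None
        if anchored_start and pos != 0:
            raise PatternSyntaxError("'<' anchor only allowed on the first element")
        rules.append(PatternRule(kind, rset, rmin, rmax,
                                 anchored_start, anchored_end))
    for r in rules[:-1]:
        if r.anchored_end:
            raise PatternSyntaxError("'>' anchor only allowed on the last element")
    return PrositePattern(accession, tuple(rules))


def find_matches(pattern: PrositePattern,
                 sequence: ProteinSequence) -> list[MotifMatch]:
    """All matches of ``pattern`` in ``sequence``, overlapping allowed.

    Every start offset is tested; variable repeats enumerate every
    expansion length (shortest first).  Matches are returned sorted by
    start, then length, then mask, with exact duplicates removed.
    """
    residues = sequence.residues
    n = len(residues)
    rules = pattern.rules
    informative = pattern.informative
    results: set[tuple[int, int, tuple[bool, ...]]] = set()

    def backtrack(rule_idx: int, pos: int, mask: list[bool]) -> None:
        if rule_idx == len(rules):
            if pattern.anchored_end and pos != n:
                return
            results.add((pos - len(mask), pos, tuple(mask)))
            return
        rule = rules[rule_idx]
        flag = informative[rule_idx]
        # consume min_repeat mandatorily, then branch per extra repeat
        p = pos
        consumed = 0
        while consumed < rule.min_repeat:
            if p >= n or not rule.accepts(residues[p]):
                return
            p += 1
            consumed += 1
        added = [flag] * rule.min_repeat
        backtrack(rule_idx + 1, p, mask + added)
        while consumed < rule.max_repeat:
            if p >= n or not rule.accepts(residues[p]):
                return
            p += 1
            consumed += 1
            added.append(flag)
            backtrack(rule_idx + 1, p, mask + added)

    starts = [0] if pattern.anchored_start else range(n + 1)
    for start in starts:
        backtrack(0, start, [])
    return [
        MotifMatch(sequence.id, s, e, pattern.accession, mask)
        for s, e, mask in sorted(results)
    ]


MotifTrack = tuple  # per-position frozenset of accessions, ungapped coords


def annotate(sequences: Sequence[ProteinSequence],
             patterns: Sequence[PrositePattern],
             all_informative: bool = False) -> list[MotifTrack]:
    """Build one collapsed motif track per sequence.

    A position is annotated with a pattern's accession when some match
    of that pattern covers it at an informative position (or at any
    position when ``all_informative``).  Matches of multiple patterns
    are collapsed into a single per-position accession set.
    """
    tracks: list[MotifTrack] = []
    for seq in sequences:
        hit: list[set] = [set() for _ in range(len(seq))]
        for pattern in patterns:
            for match in find_matches(pattern, seq):
                for offset, flag in enumerate(match.informative_mask):
                    if flag or all_informative:
                        hit[match.start + offset].add(pattern.accession)
        tracks.append(tuple(frozenset(s) for s in hit))
    return tracks


def map_track_through_gaps(track: MotifTrack, gapped_row: str) -> MotifTrack:
    """Lift an ungapped-coordinate track onto a gapped alignment row.

    The annotation of ungapped position *i* lands on the *i*-th non-gap
    column; gap columns carry empty sets.
    """
    degapped_len = sum(1 for c in gapped_row if c != "-")
    if degapped_len != len(track):
        raise ValueError(
            f"track length {len(track)} does not match degapped row "
            f"length {degapped_len}"
        )
    out = []
    i = 0
    for c in gapped_row:
        if c == "-":
            out.append(frozenset())
        else:
            out.append(frozenset(track[i]))
            i += 1
    return tuple(out)


def filter_preserved_patterns(sequences: Sequence[ProteinSequence],
                              patterns: Sequence[PrositePattern],
                              threshold: float = 0.5
                              ) -> list[PrositePattern]:
    """Keep patterns matching at least ``threshold`` of the sequences.

    A pattern is preserved when the fraction of sequences containing at
    least one match is >= threshold (boundary inclusive).
    """
    if not sequences:
        raise ValueError("empty sequence set")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    kept = []
    for pattern in patterns:
        n_hit = sum(1 for s in sequences if find_matches(pattern, s))
        if n_hit / len(sequences) >= threshold:
            kept.append(pattern)
    return kept


def read_pattern_file(text_or_stream) -> list[PrositePattern]:
    """Read motif patterns from plain text or a PROSITE flatfile.

    Plain format: one ``ACCESSION  PATTERN`` pair per line, ``#``
    comments allowed.  PROSITE flatfile records are recognized by their
    ``ID``/``AC``/``PA`` line structure; multi-line PA fields are
    concatenated.
    """
    if hasattr(text_or_stream, "read"):
        text = text_or_stream.read()
    else:
        text = text_or_stream
    lines = text.splitlines()
    if any(line.startswith(("ID ", "ID\t")) for line in lines):
        return _read_prosite_flatfile(lines)
    patterns = []
    for lineno, line in enumerate(lines, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise PatternSyntaxError(
                f"line {lineno}: expected 'ACCESSION PATTERN'"
            )
        patterns.append(parse_pattern(parts[1], parts[0]))
    if not patterns:
        raise PatternSyntaxError("no patterns found in input")
    return patterns


def _read_prosite_flatfile(lines: Iterable[str]) -> list[PrositePattern]:
    patterns = []
    accession = None
    name = None
    pa_parts: list[str] = []

    def flush():
        nonlocal accession, name, pa_parts
        if pa_parts:
            acc = accession or name or f"PATTERN{len(patterns) + 1}"
            patterns.append(parse_pattern("".join(pa_parts), acc))
        accession, name, pa_parts = None, None, []

    for line in lines:
        if line.startswith("//"):
            flush()
        elif line.startswith("ID"):
            name = line[2:].strip().rstrip(";").split(";")[0].strip()
        elif line.startswith("AC"):
            accession = line[2:].strip().rstrip(";").split(";")[0].strip()
        elif line.startswith("PA"):
            pa_parts.append(line[2:].strip())
    flush()
    if not patterns:
        raise PatternSyntaxError("no PA records found in PROSITE input")
    return patterns


def write_match_table(matches: Iterable[MotifMatch], stream,
                      sequences: Mapping[str, ProteinSequence] | None = None
                      ) -> None:
    """Emit matches as TSV with 1-based inclusive coordinates."""
    stream.write(
        "seq_id\tstart\tend\taccession\tmatched_subsequence\tinformative_mask\n"
    )
    for m in matches:
        sub = ""
        if sequences is not None and m.sequence_id in sequences:
            sub = sequences[m.sequence_id].residues[m.start:m.end]
        mask = "".join("M" if f else "*" for f in m.informative_mask)
        stream.write(
            f"{m.sequence_id}\t{m.start + 1}\t{m.end}\t{m.accession}\t{sub}\t{mask}\n"
        )
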