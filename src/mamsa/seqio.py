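"""Sequence, alignment and substitution-matrix I/O.

Reads unaligned protein sequences from FASTA, gapped alignments from
aligned FASTA or Clustal, and amino-acid substitution matrices in the
NCBI matrix format (BLOSUM62/40/30 available by name).  The canonical
gap character is ``'-'``; ``'.'`` is accepted on input and normalized.
Internally all coordinates are 0-based half-open; user-facing output is
1-based inclusive.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUITY_CODES = "XBZ"
VALID_RESIDUES = frozenset(AMINO_ACIDS + AMBIGUITY_CODES)
GAP = "-"

#: Matrices loadable by name.  The files behind these names are the NCBI
#: distributions bundled with biotite.
BUNDLED_MATRICES = ("blosum62", "blosum40", "blosum30")


class SequenceFormatError(ValueError):
    """Raised when an input stream violates a sequence-format contract."""


@dataclass(frozen=True)
class ProteinSequence:
    """An identifier plus an ungapped residue string.

    Residues are the 20 standard amino-acid letters plus the ambiguity
    codes X, B and Z.  Gap characters are illegal here: gaps only exist
    in :class:`Alignment` rows.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SequenceFormatError(f"invalid sequence id: {self.id!r}")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            if bad & {GAP, "."}:
                raise SequenceFormatError(
                    f"sequence {self.id!r}: gap character in unaligned input"
                )
            raise SequenceFormatError(
                f"sequence {self.id!r}: illegal residue characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """Rows of equal-length gapped sequences, optionally motif-annotated.

    ``tracks`` maps each row to a per-column tuple of frozensets of
    pattern accessions (empty set at gap columns and unannotated
    positions), in gapped coordinates.
    """

    ids: list[str]
    rows: list[str]
    tracks: list[tuple[frozenset, ...]] | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if self.rows:
            n = len(self.rows[0])
            for rid, row in zip(self.ids, self.rows):
                if len(row) != n:
                    raise SequenceFormatError(
                        f"row {rid!r} has length {len(row)}, expected {n}"
                    )
        if len(set(self.ids)) != len(self.ids):
            raise SequenceFormatError("duplicate row ids in alignment")
        if self.tracks is not None:
            for rid, row, track in zip(self.ids, self.rows, self.tracks):
                if len(track) != len(row):
                    raise ValueError(f"track length mismatch for row {rid!r}")
                for col, (c, ann) in enumerate(zip(row, track)):
                    if c == GAP and ann:
                        raise ValueError(
                            f"row {rid!r}: gap column {col} is motif-annotated"
                        )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, index: int) -> ProteinSequence:
        """The ungapped sequence of row ``index``."""
        return ProteinSequence(self.ids[index], self.rows[index].replace(GAP, ""))

    def sequences(self) -> list[ProteinSequence]:
        return [self.degapped(i) for i in range(self.n_rows)]

    def reordered(self, ids: Sequence[str]) -> "Alignment":
        """A copy with rows permuted into the order given by ``ids``."""
        pos = {rid: i for i, rid in enumerate(self.ids)}
        idx = [pos[r] for r in ids]
        tracks = [self.tracks[i] for i in idx] if self.tracks is not None else None
        return Alignment(list(ids), [self.rows[i] for i in idx], tracks)


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric residue substitution score table S(x, y)."""

    alphabet: str
    scores: np.ndarray = field(compare=False)
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.alphabet)
        if self.scores.shape != (n, n):
            raise ValueError("score table shape does not match alphabet")
        if not np.array_equal(self.scores, self.scores.T):
            i, j = np.argwhere(self.scores != self.scores.T)[0]
            raise ValueError(
                "asymmetric substitution matrix: "
                f"S({self.alphabet[i]},{self.alphabet[j]}) != "
                f"S({self.alphabet[j]},{self.alphabet[i]})"
            )
        object.__setattr__(
            self, "_index", {c: i for i, c in enumerate(self.alphabet)}
        )

    def score(self, x: str, y: str) -> float:
        idx = self._index
        return float(self.scores[idx[x], idx[y]])

    def __contains__(self, letter: str) -> bool:
        return letter in self._index

    def encode(self, residues: str) -> np.ndarray:
        """Residue string to integer indices into ``scores``."""
        idx = self._index
        return np.fromiter((idx[c] for c in residues), dtype=np.intp,
                           count=len(residues))


def _as_text_stream(source) -> IO[str]:
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def read_fasta(source) -> list[ProteinSequence]:
    """Read unaligned protein sequences from FASTA text or a stream.

    Lowercase residues are uppercased.  Empty input, duplicate ids, gap
    characters and illegal residues are reported as
    :class:`SequenceFormatError`.
    """
    records = list(SeqIO.parse(_as_text_stream(source), "fasta"))
    if not records:
        raise SequenceFormatError("no FASTA records found in input")
    seqs: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SequenceFormatError(f"duplicate sequence id: {rec.id!r}")
        seen.add(rec.id)
        seqs.append(ProteinSequence(rec.id, str(rec.seq).upper()))
    return seqs


def read_alignment(source, dialect: str = "afa") -> Alignment:
    """Read a gapped alignment from aligned FASTA (``afa``) or Clustal.

    ``'.'`` gaps are normalized to ``'-'``.  Ragged rows raise an error
    naming the offending row.
    """
    if dialect not in ("afa", "clustal"):
        raise ValueError(f"unknown alignment dialect: {dialect!r}")
    stream = _as_text_stream(source)
    if dialect == "afa":
        records = list(SeqIO.parse(stream, "fasta"))
    else:
        records = list(AlignIO.read(stream, "clustal"))
    if not records:
        raise SequenceFormatError("no alignment rows found in input")
    ids = [rec.id for rec in records]
    rows = [str(rec.seq).upper().replace(".", GAP) for rec in records]
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        n = len(rows[0])
        for rid, row in zip(ids, rows):
            if len(row) != n:
                raise SequenceFormatError(
                    f"ragged alignment: row {rid!r} has length {len(row)}, "
                    f"expected {n}"
                )
    aln = Alignment(ids, rows)
    for i in range(aln.n_rows):
        aln.degapped(i)  # validates residues
    return aln


def write_alignment(alignment: Alignment, stream: IO[str],
                    dialect: str = "afa") -> None:
    """Write an alignment as aligned FASTA or Clustal."""
    if not alignment.rows:
        raise SequenceFormatError("refusing to write an empty alignment")
    records = [
        SeqRecord(Seq(row), id=rid, description="")
        for rid, row in zip(alignment.ids, alignment.rows)
    ]
    if dialect == "afa":
        SeqIO.write(records, stream, "fasta-2line")
    elif dialect == "clustal":
        from Bio.Align import MultipleSeqAlignment

        AlignIO.write(MultipleSeqAlignment(records), stream, "clustal")
    else:
        raise ValueError(f"unknown alignment dialect: {dialect!r}")


def write_track_table(alignment: Alignment, stream: IO[str]) -> None:
    """Emit per-position motif annotations as TSV (1-based columns)."""
    if alignment.tracks is None:
        raise ValueError("alignment carries no motif tracks")
    stream.write("seq_id\tcolumn\taccessions\n")
    for rid, track in zip(alignment.ids, alignment.tracks):
        for col, ann in enumerate(track):
            if ann:
                stream.write(f"{rid}\t{col + 1}\t{','.join(sorted(ann))}\n")


def load_substitution_matrix(name_or_stream) -> SubstitutionMatrix:
    """Load a substitution matrix by name or from NCBI-format text.

    Accepted names: ``blosum62``, ``blosum40``, ``blosum30`` (the NCBI
    distributions, via biotite's bundled data files).  Any other string
    or stream is parsed as NCBI matrix format text.
    """
    if isinstance(name_or_stream, str) and name_or_stream.lower() in BUNDLED_MATRICES:
        name = name_or_stream.lower()
        import biotite.sequence as bseq
        import biotite.sequence.align as balign

        alph = bseq.ProteinSequence.alphabet
        mat = balign.SubstitutionMatrix(alph, alph, name.upper())
        letters = "".join(alph.get_symbols())
        return SubstitutionMatrix(
            letters, np.asarray(mat.score_matrix(), dtype=float), name=name
        )
    mat = substitution_matrices.read(_as_text_stream(name_or_stream))
    letters = "".join(mat.alphabet)
    scores = np.asarray(mat, dtype=float)
    if not np.array_equal(scores, scores.T):
        raise ValueError("asymmetric substitution matrix")
    return SubstitutionMatrix(letters, scores)
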