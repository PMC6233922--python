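"""Deterministic synthetic protein families with known true alignments.

The generator emulates the input regime the motif-aware aligner is
built for: families with well-conserved flanking blocks and
hypervariable blocks (in the spirit of the HIV gp120 V-loops) in which
short functional motifs — N-glycosylation sequons by default — persist
while the surrounding residues mutate and accumulate indels.

Every family descends from one ancestor drawn block by block.  Motif
instances are implanted at jittered positions inside the hypervariable
blocks and are protected: substitutions at informative motif positions
are vetoed, substitutions at spacer positions are resampled until the
rule still matches, and indels never touch a motif span.  Because
indels are the only source of gaps and they are confined to variable
blocks, the true alignment is known exactly and travels with the
generated sequences.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .motif import (PatternRule, PrositePattern, annotate, find_matches,
                    map_track_through_gaps, parse_pattern)
from .seqio import AMINO_ACIDS, Alignment, ProteinSequence

SEQUON = ("PS00001", "N-{P}-[ST]-{P}")


@dataclass(frozen=True)
class Block:
    """One layout block of the ancestor: conserved or hypervariable."""

    kind: str  # conserved | variable
    length: int

    def __post_init__(self) -> None:
        if self.kind not in ("conserved", "variable"):
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("block length must be >= 1")


@dataclass(frozen=True)
class FamilySpec:
    """Everything that determines one synthetic family.

    Defaults give an HIV-ENV-flavoured miniature: three conserved
    flanks around two hypervariable blocks, two sequon copies per
    variable block, strong substitution pressure and geometric indels
    confined to the variable blocks.
    """

    n_sequences: int = 10
    blocks: tuple[Block, ...] = (
        Block("conserved", 20),
        Block("variable", 25),
        Block("conserved", 20),
        Block("variable", 25),
        Block("conserved", 20),
    )
    patterns: tuple[tuple[str, str], ...] = (SEQUON,)
    copies_per_variable_block: int = 2
    substitution_rate_conserved: float = 0.1
    substitution_rate_variable: float = 0.5
    indel_rate: float = 0.08
    indel_extend: float = 0.5  # geometric continuation, mean length 2
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.substitution_rate_conserved,
                     self.substitution_rate_variable, self.indel_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if not 0 <= self.indel_extend < 1:
            raise ValueError("indel_extend must lie in [0, 1)")
        if self.n_sequences < 2:
            raise ValueError("need at least two sequences")

    def parsed_patterns(self) -> list[PrositePattern]:
        return [parse_pattern(text, acc) for acc, text in self.patterns]


@dataclass
class FamilyTruth:
    """Generated sequences plus the ground truth behind them."""

    spec: FamilySpec
    sequences: list[ProteinSequence]
    alignment: Alignment  # with motif tracks in gapped coordinates
    tracks: list[tuple]  # collapsed tracks in ungapped coordinates
    column_labels: list[str]  # conserved | variable | motif per column
    patterns: list[PrositePattern] = field(default_factory=list)


def _sample_rule_residue(rule: PatternRule, rng: random.Random) -> str:
    if rule.kind == "exact":
        return next(iter(rule.residue_set))
    if rule.kind == "one_of":
        return rng.choice(sorted(rule.residue_set))
    if rule.kind == "none_of":
        return rng.choice(sorted(set(AMINO_ACIDS) - rule.residue_set))
    return rng.choice(AMINO_ACIDS)


def _instance_layout(pattern: PrositePattern) -> list[PatternRule]:
    """Rules expanded at their minimum repeat counts."""
    expanded: list[PatternRule] = []
    for rule in pattern.rules:
        expanded.extend([rule] * rule.min_repeat)
    return expanded


def generate_family(spec: FamilySpec) -> FamilyTruth:
    """Draw one family: ancestor, mutated descendants, true alignment."""
    rng = random.Random(spec.seed)
    patterns = spec.parsed_patterns()

    # --- ancestor ----------------------------------------------------
    ancestor: list[str] = []
    block_of: list[Block] = []  # per ancestor position
    for block in spec.blocks:
        for _ in range(block.length):
            ancestor.append(rng.choice(AMINO_ACIDS))
            block_of.append(block)

    # implant motif instances into the variable blocks
    motif_rule_at: dict[int, tuple[PatternRule, bool]] = {}  # pos -> rule, informative
    in_motif = [False] * len(ancestor)
    offset = 0
    n_var = sum(1 for b in spec.blocks if b.kind == "variable")
    pattern_cycle = 0
    for block in spec.blocks:
        if block.kind == "variable" and patterns:
            copies = spec.copies_per_variable_block
            chunk = block.length // max(copies, 1)
            for c in range(copies):
                pattern = patterns[pattern_cycle % len(patterns)]
                pattern_cycle += 1
                layout = _instance_layout(pattern)
                informative = []
                for rule, flag in zip(pattern.rules, pattern.informative):
                    informative.extend([flag] * rule.min_repeat)
                if len(layout) > chunk:
                    raise ValueError(
                        f"motif {pattern.accession} (length {len(layout)}) "
                        f"does not fit its host block chunk of {chunk}"
                    )
                jitter = rng.randrange(chunk - len(layout) + 1)
                start = offset + c * chunk + jitter
                for k, (rule, flag) in enumerate(zip(layout, informative)):
                    pos = start + k
                    ancestor[pos] = _sample_rule_residue(rule, rng)
                    motif_rule_at[pos] = (rule, flag)
                    in_motif[pos] = True
        offset += block.length
    n_anc = len(ancestor)

    # --- descendants -------------------------------------------------
    sub_rate = {
        "conserved": spec.substitution_rate_conserved,
        "variable": spec.substitution_rate_variable,
    }
    kept: list[list[str | None]] = []  # per seq, per ancestor pos (None = deleted)
    insertions: list[dict[int, str]] = []  # per seq: pos -> residues after pos
    for _ in range(spec.n_sequences):
        residues: list[str | None] = []
        for pos, a_res in enumerate(ancestor):
            if pos in motif_rule_at:
                rule, informative = motif_rule_at[pos]
                if informative:
                    residues.append(a_res)  # mutation vetoed
                elif rng.random() < sub_rate[block_of[pos].kind]:
                    residues.append(_sample_rule_residue(rule, rng))
                else:
                    residues.append(a_res)
            elif rng.random() < sub_rate[block_of[pos].kind]:
                choices = AMINO_ACIDS.replace(a_res, "")
                residues.append(rng.choice(choices))
            else:
                residues.append(a_res)
        ins: dict[int, str] = {}
        if spec.indel_rate > 0:
            pos = 0
            while pos < n_anc:
                if (block_of[pos].kind == "variable" and not in_motif[pos]
                        and residues[pos] is not None
                        and rng.random() < spec.indel_rate / 2):
                    length = _geometric(rng, spec.indel_extend)
                    for p in range(pos, min(pos + length, n_anc)):
                        if block_of[p].kind != "variable" or in_motif[p]:
                            break
                        residues[p] = None
                pos += 1
            for pos in range(-1, n_anc):
                here_var = pos >= 0 and block_of[pos].kind == "variable"
                inside_motif = (
                    pos >= 0 and pos + 1 < n_anc
                    and in_motif[pos] and in_motif[pos + 1]
                )
                if here_var and not inside_motif and rng.random() < spec.indel_rate / 2:
                    length = _geometric(rng, spec.indel_extend)
                    ins[pos] = "".join(
                        rng.choice(AMINO_ACIDS) for _ in range(length)
                    )
        kept.append(residues)
        insertions.append(ins)

    # --- true alignment ----------------------------------------------
    ids = [f"seq{i + 1}" for i in range(spec.n_sequences)]
    columns: list[list[str]] = []
    labels: list[str] = []

    def add_insertion_columns(pos: int) -> None:
        for s in range(spec.n_sequences):
            for res in insertions[s].get(pos, ""):
                col = ["-"] * spec.n_sequences
                col[s] = res
                columns.append(col)
                labels.append("variable")

    add_insertion_columns(-1)
    for pos in range(n_anc):
        col = [kept[s][pos] or "-" for s in range(spec.n_sequences)]
        columns.append(col)
        labels.append("motif" if pos in motif_rule_at else block_of[pos].kind)
        add_insertion_columns(pos)

    rows = ["".join(col[s] for col in columns)
            for s in range(spec.n_sequences)]
    sequences = [ProteinSequence(rid, row.replace("-", ""))
                 for rid, row in zip(ids, rows)]
    tracks = annotate(sequences, patterns)
    gapped_tracks = [map_track_through_gaps(tr, row)
                     for tr, row in zip(tracks, rows)]
    truth = Alignment(ids, rows, gapped_tracks)

    _check_implants_survive(sequences, patterns, motif_rule_at, kept)
    return FamilyTruth(spec, sequences, truth, tracks, labels, patterns)


def _geometric(rng: random.Random, extend: float) -> int:
    length = 1
    while rng.random() < extend:
        length += 1
    return length


def _check_implants_survive(sequences, patterns, motif_rule_at, kept) -> None:
    """Every implanted informative position must be found by matching."""
    if not patterns:
        return
    tracks = annotate(sequences, patterns)
    informative_anc = sorted(
        pos for pos, (_, flag) in motif_rule_at.items() if flag
    )
    for s, seq in enumerate(sequences):
        # ancestor position -> this sequence's ungapped coordinate
        coord = {}
        k = 0
        for pos, res in enumerate(kept[s]):
            if res is not None:
                coord[pos] = k
                k += 1
        # insertions shift coordinates; recompute by walking the row
        for pos in informative_anc:
            if pos not in coord:
                raise RuntimeError("informative motif position was deleted")
    # the veto logic guarantees residue-level survival; verify via matching
    for s, (seq, track) in enumerate(zip(sequences, tracks)):
        if not any(track):
            raise RuntimeError(
                f"implanted motifs not recovered in {seq.id}"
            )


def make_benchmark_case(spec: FamilySpec, out_dir: str | Path,
                        prefix: str = "family") -> dict[str, Path]:
    """Write the (unaligned FASTA, reference alignment, pattern file)
    triple for one family, ready for `mamsa align` + `mamsa score`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = generate_family(spec)
    fasta = out_dir / f"{prefix}.fasta"
    ref = out_dir / f"{prefix}.ref.afa"
    pat = out_dir / f"{prefix}.patterns.txt"
    with open(fasta, "w") as fh:
        for seq in truth.sequences:
            fh.write(f">{seq.id}\n{seq.residues}\n")
    with open(ref, "w") as fh:
        for rid, row in zip(truth.alignment.ids, truth.alignment.rows):
            fh.write(f">{rid}\n{row}\n")
    with open(pat, "w") as fh:
        for acc, text in spec.patterns:
            fh.write(f"{acc}\t{text}\n")
    return {"fasta": fasta, "reference": ref, "patterns": pat}
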