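import random

import pytest

from mamsa import (AlignParams, GapPenalty, ProteinSequence,
                   load_substitution_matrix, parse_pattern)


@pytest.fixture(scope="session")
def blosum62():
    return load_substitution_matrix("blosum62")


@pytest.fixture(scope="session")
def sequon():
    """The N-glycosylation sequon pattern N-{P}-[ST]-{P}."""
    return parse_pattern("N-{P}-[ST]-{P}", "PS00001")


@pytest.fixture
def make_params(blosum62):
    def _make(alpha=0.0, mode="global", gap_mode="affine",
              open_=-11.0, extend=-1.0):
        if gap_mode == "linear":
            gaps = GapPenalty("linear", extend)
        else:
            gaps = GapPenalty("affine", extend, open_)
        return AlignParams(blosum62, gaps, alpha, mode)

    return _make


def random_sequence(rng: random.Random, length: int,
                    alphabet: str = "ACDEFGHIKLMNPQRSTVWY",
                    seq_id: str = "s") -> ProteinSequence:
    return ProteinSequence(
        seq_id, "".join(rng.choice(alphabet) for _ in range(length))
    )


def random_track(rng: random.Random, length: int, p: float = 0.3,
                 accessions=("PS1", "PS2")):
    """Random per-position accession sets, for DP oracle tests."""
    return tuple(
        frozenset(a for a in accessions if rng.random() < p)
        for _ in range(length)
    )
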