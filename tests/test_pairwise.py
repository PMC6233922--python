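import math
import random

import pytest

from mamsa import (AlignParams, GapPenalty, ProteinSequence, align_pair,
                   align_pair_general, annotate, default_params, motif_bonus,
                   parse_pattern)
from mamsa.pairwise import score_path

from conftest import random_sequence, random_track
from oracles import best_alignment_score, substitution_table


class TestMotifBonus:
    def test_shared_accession_earns_alpha(self):
        assert motif_bonus(frozenset({"PS00001"}), frozenset({"PS00001"}),
                           20) == 20

    def test_no_shared_accession_earns_nothing(self):
        assert motif_bonus(frozenset({"PS00001"}), frozenset(), 20) == 0
        assert motif_bonus(frozenset({"A"}), frozenset({"B"}), 20) == 0

    def test_alpha_zero_always_zero(self):
        assert motif_bonus(frozenset({"A"}), frozenset({"A"}), 0) == 0


class TestAlignPair:
    def test_identical_dipeptide(self, make_params):
        r = align_pair(ProteinSequence("a", "AA"), ProteinSequence("b", "AA"),
                       make_params(alpha=0))
        assert r.score == 8  # 2 x S(A,A) = 4 under BLOSUM62
        assert all(op[0] == "M" for op in r.path)

    def test_path_rescoring_matches_dp_score(self, make_params):
        rng = random.Random(11)
        for _ in range(60):
            a = random_sequence(rng, rng.randint(1, 15), seq_id="a")
            b = random_sequence(rng, rng.randint(1, 15), seq_id="b")
            ta = random_track(rng, len(a))
            tb = random_track(rng, len(b))
            for mode in ("global", "semiglobal"):
                params = make_params(alpha=7.5, mode=mode)
                r = align_pair(a, b, params, ta, tb)
                assert math.isclose(score_path(r, params), r.score)
                degapped = r.as_alignment()
                assert degapped.degapped(0).residues == a.residues
                assert degapped.degapped(1).residues == b.residues

    def test_symmetry(self, make_params):
        rng = random.Random(5)
        for _ in range(40):
            a = random_sequence(rng, rng.randint(1, 12), seq_id="a")
            b = random_sequence(rng, rng.randint(1, 12), seq_id="b")
            for mode in ("global", "semiglobal"):
                params = make_params(mode=mode)
                assert math.isclose(
                    align_pair(a, b, params).score,
                    align_pair(b, a, params).score,
                )

    def test_semiglobal_never_below_global(self, make_params):
        rng = random.Random(9)
        for _ in range(40):
            a = random_sequence(rng, rng.randint(1, 12), seq_id="a")
            b = random_sequence(rng, rng.randint(1, 12), seq_id="b")
            assert align_pair(a, b, make_params(mode="semiglobal")).score >= \
                align_pair(a, b, make_params(mode="global")).score

    def test_empty_sequence_contract(self, make_params):
        a = ProteinSequence("a", "")
        b = ProteinSequence("b", "ACD")
        params = make_params()
        r = align_pair(a, b, params)
        assert r.score == params.gaps.cost(3) == -13
        assert [op[0] for op in r.path] == ["GA"] * 3
        assert align_pair(a, b, make_params(mode="semiglobal")).score == 0

    def test_alpha_zero_reverts_to_plain_needleman_wunsch(self, make_params):
        from Bio import Align as BioAlign

        aligner = BioAlign.PairwiseAligner()
        aligner.substitution_matrix = \
            BioAlign.substitution_matrices.load("BLOSUM62")
        aligner.mode = "global"
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        rng = random.Random(17)
        params = make_params(alpha=0)
        for _ in range(40):
            a = random_sequence(rng, rng.randint(1, 25), seq_id="a")
            b = random_sequence(rng, rng.randint(1, 25), seq_id="b")
            assert align_pair(a, b, params).score == \
                aligner.score(a.residues, b.residues)

    def test_large_alpha_flips_motif_misalignment(self, make_params):
        # A-A motif regime under BLOSUM62, open -11 / extend -1: the
        # alpha = 0 optimum leaves the two AA blocks unpaired; raising
        # alpha flips the optimum to pair both motif positions.
        pat = parse_pattern("A-A", "PSAA")
        sa = ProteinSequence("a", "WAAWYF")
        sb = ProteinSequence("b", "WYFWAA")
        (ta,) = annotate([sa], [pat])
        (tb,) = annotate([sb], [pat])
        counts = {}
        for alpha in (0, 20):
            r = align_pair(sa, sb, make_params(alpha=alpha), ta, tb)
            counts[alpha] = r.motif_pair_columns()
            # cross-check optimality against exhaustive enumeration
            sub = substitution_table(sa.residues, sb.residues,
                                     make_params().matrix, alpha, ta, tb)
            assert math.isclose(
                r.score,
                best_alignment_score(len(sa), len(sb), sub,
                                     make_params().gaps.cost, "global"),
            )
        assert counts[0] == 0 and counts[20] == 2

    def test_motif_pair_count_monotone_in_alpha(self, make_params):
        rng = random.Random(23)
        for _ in range(10):
            a = random_sequence(rng, 20, seq_id="a")
            b = random_sequence(rng, 20, seq_id="b")
            ta = random_track(rng, 20)
            tb = random_track(rng, 20)
            last = -1
            for alpha in range(0, 55, 5):
                r = align_pair(a, b, make_params(alpha=alpha), ta, tb)
                count = r.motif_pair_columns()
                assert count >= last
                last = count

    def test_general_gap_mode_rejected(self, make_params, blosum62):
        params = AlignParams(blosum62, GapPenalty("general", g=lambda l: -l),
                             0, "global")
        with pytest.raises(ValueError, match="linear or affine"):
            align_pair(ProteinSequence("a", "A"), ProteinSequence("b", "A"),
                       params)


class TestExhaustiveOracle:
    """DP score equals enumeration of every alignment on small inputs."""

    @pytest.mark.parametrize("mode", ["global", "semiglobal"])
    @pytest.mark.parametrize("gap_mode", ["linear", "affine"])
    def test_dp_equals_enumeration(self, mode, gap_mode, make_params):
        rng = random.Random(hash((mode, gap_mode)) & 0xFFFF)
        for _ in range(60):
            a = random_sequence(rng, rng.randint(0, 7), "ACDE", "a")
            b = random_sequence(rng, rng.randint(0, 7), "ACDE", "b")
            ta = random_track(rng, len(a))
            tb = random_track(rng, len(b))
            alpha = rng.choice([0, 5, 10])
            params = make_params(alpha=alpha, mode=mode, gap_mode=gap_mode)
            got = align_pair(a, b, params, ta, tb).score
            sub = substitution_table(a.residues, b.residues, params.matrix,
                                     alpha, ta, tb)
            want = best_alignment_score(len(a), len(b), sub,
                                        params.gaps.cost, mode)
            assert math.isclose(got, want), (a.residues, b.residues)


class TestGeneralKernel:
    def test_equals_affine_kernel(self, make_params):
        rng = random.Random(31)
        for _ in range(40):
            a = random_sequence(rng, rng.randint(1, 12), seq_id="a")
            b = random_sequence(rng, rng.randint(1, 12), seq_id="b")
            ta = random_track(rng, len(a))
            tb = random_track(rng, len(b))
            for mode in ("global", "semiglobal"):
                params = make_params(alpha=5, mode=mode)
                assert math.isclose(
                    align_pair(a, b, params, ta, tb).score,
                    align_pair_general(a, b, params, ta, tb).score,
                )

    def test_concave_gap_function_beats_matching_affine(self, blosum62):
        # g(l) = -5*ceil(l/2) dominates the affine e=-5, d=-5 penalty,
        # so the general-kernel optimum can only be higher.
        concave = AlignParams(
            blosum62,
            GapPenalty("general", g=lambda l: -5 * math.ceil(l / 2)),
            0, "global",
        )
        affine = AlignParams(blosum62, GapPenalty("affine", -5.0, -5.0),
                             0, "global")
        rng = random.Random(37)
        for _ in range(20):
            a = random_sequence(rng, rng.randint(1, 9), seq_id="a")
            b = random_sequence(rng, rng.randint(1, 9), seq_id="b")
            assert align_pair_general(a, b, concave).score >= \
                align_pair(a, b, affine).score

    def test_empty_vs_sequence_pays_full_gap(self, blosum62):
        params = AlignParams(blosum62, GapPenalty("general", g=lambda l: -4 * l),
                             0, "global")
        r = align_pair_general(ProteinSequence("a", ""),
                               ProteinSequence("b", "ACD"), params)
        assert r.score == -12

    def test_bad_gap_function_rejected(self, blosum62):
        with pytest.raises(ValueError, match="g\\(0\\)"):
            GapPenalty("general", g=lambda l: -l - 1)
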