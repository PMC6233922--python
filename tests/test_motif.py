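import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mamsa import (ProteinSequence, annotate, filter_preserved_patterns,
                   find_matches, map_track_through_gaps, parse_pattern,
                   read_pattern_file, rule_is_informative)
from mamsa.motif import PatternRule, PatternSyntaxError

from conftest import random_sequence
from oracles import regex_matches


class TestParsePattern:
    def test_sequon_rules_and_informativeness(self):
        p = parse_pattern("N-{P}-[ST]-{P}", "PS00001")
        assert [r.kind for r in p.rules] == \
            ["exact", "none_of", "one_of", "none_of"]
        assert p.informative == (True, False, True, False)

    def test_spacer_repeat_uninformative(self):
        p = parse_pattern("N-x(8)-N")
        assert [r.kind for r in p.rules] == ["exact", "any", "exact"]
        assert p.rules[1].min_repeat == p.rules[1].max_repeat == 8
        assert p.informative == (True, False, True)

    def test_single_residue(self):
        p = parse_pattern("A")
        assert len(p.rules) == 1 and p.informative == (True,)

    def test_variable_repeat_and_anchors(self):
        p = parse_pattern("<A-x(2,4)-[DE]>")
        assert p.anchored_start and p.anchored_end
        assert (p.rules[1].min_repeat, p.rules[1].max_repeat) == (2, 4)

    def test_prosite_flatfile_trailing_dot(self):
        p = parse_pattern("N-{P}-[ST]-{P}.")
        assert len(p.rules) == 4

    @pytest.mark.parametrize("bad", [
        "", "N--A", "[]-A", "{}-A", "N-(3)", "N-[S", "A-x(3,2)", "1-A",
        "A->-B",
    ])
    def test_malformed_patterns_rejected(self, bad):
        with pytest.raises(PatternSyntaxError):
            parse_pattern(bad)


class TestRuleInformativeness:
    @pytest.mark.parametrize("pattern,idx,expected", [
        ("{P}-A", 0, False),      # excludes only one type
        ("[AW]-A", 0, True),      # includes two types
        ("[ACDEFGHIKL]-A", 0, False),  # exactly 10 included: strict rule
        ("[ACDEFGHIK]-A", 0, True),    # 9 included, 11 excluded
        ("x-A", 0, False),
        ("{ACDEFGHIKLM}-A", 0, True),  # excludes 11
    ])
    def test_excluded_must_exceed_included(self, pattern, idx, expected):
        p = parse_pattern(pattern)
        assert rule_is_informative(p.rules[idx]) is expected


class TestFindMatches:
    def test_sequon_match_with_mask(self, sequon):
        # NNTT at offset 1 and, overlapping, NTTG at offset 2
        ms = find_matches(sequon, ProteinSequence("s", "ANNTTG"))
        assert [(m.start, m.end) for m in ms] == [(1, 5), (2, 6)]
        assert ms[0].informative_mask == (True, False, True, False)

    def test_proline_blocks_match(self, sequon):
        assert find_matches(sequon, ProteinSequence("s", "NPSA")) == []

    def test_empty_sequence(self, sequon):
        assert find_matches(sequon, ProteinSequence("s", "")) == []

    def test_overlapping_matches_all_reported(self, sequon):
        # NNSS contains sequon matches at 0 and, overlapping, none at 1
        ms = find_matches(sequon, ProteinSequence("s", "NNSSTA"))
        assert [(m.start, m.end) for m in ms] == [(0, 4), (1, 5)]

    def test_variable_repeat_enumerates_every_length(self):
        p = parse_pattern("A-x(1,3)-C")
        ms = find_matches(p, ProteinSequence("s", "AGGGC"))
        assert [(m.start, m.end) for m in ms] == [(0, 5)]
        ms = find_matches(p, ProteinSequence("s", "ACCCC"))
        assert [(m.start, m.end) for m in ms] == [(0, 3), (0, 4), (0, 5)]

    def test_anchored_pattern(self):
        assert find_matches(parse_pattern("<M-A"),
                            ProteinSequence("s", "MAMA")) != []
        assert find_matches(parse_pattern("<A-M"),
                            ProteinSequence("s", "MAMA")) == []
        ms = find_matches(parse_pattern("M-A>"), ProteinSequence("s", "MAMA"))
        assert [(m.start, m.end) for m in ms] == [(2, 4)]

    def test_ambiguity_codes_only_satisfy_any(self):
        assert find_matches(parse_pattern("N"),
                            ProteinSequence("s", "XBZ")) == []
        assert find_matches(parse_pattern("{P}"),
                            ProteinSequence("s", "X")) == []
        ms = find_matches(parse_pattern("x"), ProteinSequence("s", "X"))
        assert [(m.start, m.end) for m in ms] == [(0, 1)]

    def test_agrees_with_regex_oracle_on_random_instances(self):
        rng = random.Random(42)
        elements = ["A", "C", "G", "N", "x", "[AC]", "[NG]", "{A}", "{ACG}"]
        for _ in range(300):
            n_rules = rng.randint(1, 6)
            parts = []
            for _ in range(n_rules):
                el = rng.choice(elements)
                if rng.random() < 0.3:
                    lo = rng.randint(1, 2)
                    hi = rng.randint(lo, 3)
                    el += f"({lo})" if lo == hi else f"({lo},{hi})"
                parts.append(el)
            text = "-".join(parts)
            if rng.random() < 0.15:
                text = "<" + text
            if rng.random() < 0.15:
                text += ">"
            pattern = parse_pattern(text)
            seq = random_sequence(rng, rng.randint(0, 30), "ACGN")
            got = [(m.start, m.end, m.informative_mask)
                   for m in find_matches(pattern, seq)]
            assert got == regex_matches(pattern, seq), text


class TestAnnotate:
    def test_default_mode_informative_positions_only(self, sequon):
        [track] = annotate([ProteinSequence("s", "NAST")], [sequon])
        assert [i for i, a in enumerate(track) if a] == [0, 2]
        assert track[0] == {"PS00001"}

    def test_all_informative_covers_whole_span(self, sequon):
        [track] = annotate([ProteinSequence("s", "NAST")], [sequon],
                           all_informative=True)
        assert [i for i, a in enumerate(track) if a] == [0, 1, 2, 3]

    def test_no_match_empty_track(self, sequon):
        [track] = annotate([ProteinSequence("s", "GGGG")], [sequon])
        assert not any(track)

    def test_collapse_idempotent(self, sequon):
        seq = ProteinSequence("s", "NASTNAST")
        once = annotate([seq], [sequon])
        twice = annotate([seq], [sequon, sequon])
        assert once == twice

    def test_all_informative_is_superset(self, sequon):
        rng = random.Random(7)
        for _ in range(25):
            seq = random_sequence(rng, 25, "NASTGP")
            [dflt] = annotate([seq], [sequon])
            [full] = annotate([seq], [sequon], all_informative=True)
            for d, f in zip(dflt, full):
                assert d <= f


class TestTrackMapping:
    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from("NAST-"), max_size=30))
    def test_annotations_land_on_non_gap_columns_only(self, chars):
        row = "".join(chars)
        n = sum(1 for c in row if c != "-")
        track = tuple(
            frozenset({"P1"}) if i % 2 else frozenset() for i in range(n)
        )
        mapped = map_track_through_gaps(track, row)
        assert len(mapped) == len(row)
        assert all(not ann for c, ann in zip(row, mapped) if c == "-")
        assert sum(1 for a in mapped if a) == sum(1 for a in track if a)


    def test_shift_by_gap(self):
        track = (frozenset({"P1"}), frozenset())
        assert map_track_through_gaps(track, "-NA") == \
            (frozenset(), frozenset({"P1"}), frozenset())

    def test_empty_track(self):
        track = (frozenset(), frozenset())
        assert map_track_through_gaps(track, "N-A") == \
            (frozenset(), frozenset(), frozenset())

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            map_track_through_gaps((frozenset(),), "NA")


class TestPreservedPatternFilter:
    def test_kept_dropped_and_boundary(self, sequon):
        seqs = [ProteinSequence(f"s{i}", r) for i, r in
                enumerate(["NASTG", "GNATA", "ANCSA", "GGGGG"])]
        other = parse_pattern("W-W", "PSWW")
        assert filter_preserved_patterns(seqs, [sequon, other]) == [sequon]
        # 3 of 4 >= 0.5 kept; in-all at threshold 1.0 also kept
        all_hit = [s for s in seqs if find_matches(sequon, s)]
        assert filter_preserved_patterns(all_hit, [sequon], 1.0) == [sequon]

    def test_empty_sequence_set_rejected(self, sequon):
        with pytest.raises(ValueError):
            filter_preserved_patterns([], [sequon])


class TestPatternFiles:
    def test_plain_two_column_format(self):
        pats = read_pattern_file("# demo\nPS00001\tN-{P}-[ST]-{P}\nPSWW W-W\n")
        assert [p.accession for p in pats] == ["PS00001", "PSWW"]

    def test_prosite_flatfile_records(self):
        text = (
            "ID   ASN_GLYCOSYLATION; PATTERN.\n"
            "AC   PS00001;\n"
            "PA   N-{P}-[ST]-\n"
            "PA   {P}.\n"
            "//\n"
        )
        [p] = read_pattern_file(text)
        assert p.accession == "PS00001" and len(p.rules) == 4
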