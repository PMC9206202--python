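"""Pattern induction, the library, subsumption and enrichment."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phenossu as ph
from phenossu.patterns import (
    PatternLibrary,
    RegexPattern,
    consolidate,
    filter_interpretable,
    load_library,
    parse_pattern,
    reduce_segments,
    save_library,
    units_covered,
)


class TestReduceSegments:
    @pytest.mark.parametrize(
        "segments,expected",
        [
            (["AP", "AAP", "AAAP", "AAAAP"], {"A+P"}),
            (["SLNU", "LNU"], {"S*LNU"}),
            (["AP"], {"AP"}),
            (["APCPCP"], {"A+P(CP)+"}),
            (["APCP", "APCPCP", "AAPCP"], {"A+P(CP)+"}),
            (["SLR", "LR"], {"S*LR"}),
            (["PCA", "APCA", "APA", "PA", "APCAA"], {"A*PC*A+"}),
            # mixed attribute/phenotype multiplicity separates into two axes
            (["AP", "AAP", "AAAP", "APP", "APPP"], {"A+P", "AP+"}),
        ],
    )
    def test_abstraction(self, segments, expected):
        patterns = reduce_segments(segments)
        assert {p.pattern for p in patterns} == expected

    def test_support_counts_merged_segments(self):
        patterns = reduce_segments(["AP", "AAP", "AAAP", "AAAAP"])
        assert patterns[0].support == 4

    def test_segment_with_O_rejected(self):
        with pytest.raises(ValueError, match="contains O"):
            reduce_segments(["OAP"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            reduce_segments([])

    def test_boundary_punctuation_trimmed(self):
        patterns = reduce_segments(["APC", "CAP"])
        assert {p.pattern for p in patterns} == {"AP"}

    def test_uninterpretable_core_skipped(self):
        assert reduce_segments(["CC", "AA", "PC"]) == []

    @given(
        st.lists(
            st.text(alphabet="AP", min_size=2, max_size=6).filter(
                lambda s: set(s) & {"P"}
            ),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_soundness_property(self, segments):
        """Every source segment matches the pattern it was reduced into."""
        patterns = reduce_segments(segments)
        covered = set()
        for p in patterns:
            for seg in p.segments:
                assert p.matches(seg)
                covered.add(seg)
        expected = {s for s in segments if set(s.strip("C")) & {"P", "L"} and len(s.strip("C")) >= 2}
        assert expected <= covered


class TestSubsumption:
    @pytest.mark.parametrize(
        "a,b,result",
        [
            ("AP", "A+P", True),
            ("AAP", "A+P", True),
            ("A+P", "AP", False),
            ("A+P", "A*PC*A+", False),
            ("LNU", "S*LNU", True),
            ("AP(CP)+", "A+P(CP)+", True),
            ("AP+", "A+P", False),
            ("PA", "A*PC*A+", True),
        ],
    )
    def test_structural_coverage(self, a, b, result):
        assert units_covered(parse_pattern(a), parse_pattern(b)) is result

    def test_consolidate_drops_specializations(self):
        patterns = [
            RegexPattern("A+P", "phrase-based", support=3),
            RegexPattern("AP", "phrase-based", support=2),
            RegexPattern("S*LNU", "logic-based", support=1),
        ]
        kept = consolidate(patterns)
        assert {p.pattern for p in kept} == {"A+P", "S*LNU"}
        assert next(p for p in kept if p.pattern == "A+P").support == 5


class TestBuiltinLibrary:
    def test_six_classes(self, library):
        assert len(library) == 6
        categories = [p.category for p in library]
        assert categories.count("phrase-based") == 4
        assert categories.count("logic-based") == 2
        assert all(p.provenance == "builtin" for p in library)

    @pytest.mark.parametrize(
        "word,pattern",
        [
            ("AAAAP", "A+P"),
            ("APCP", "A+P(CP)+"),
            ("SLR", "S*LR"),
            ("LNU", "S*LNU"),
            ("APP", "AP+"),
            ("PCA", "A*PC*A+"),
        ],
    )
    def test_worked_words_match(self, library, word, pattern):
        target = next(p for p in library if p.pattern == pattern)
        assert target.matches(word)

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValueError, match="no P"):
            RegexPattern("A+C", "phrase-based")
        with pytest.raises(ValueError, match="no L"):
            RegexPattern("SNU", "logic-based")

    def test_source_segment_must_match(self):
        with pytest.raises(ValueError, match="does not match"):
            RegexPattern("A+P", "phrase-based", segments=("PPA",))

    def test_round_trip(self, library, tmp_path):
        path = tmp_path / "lib.tsv"
        save_library(library, path)
        reloaded = load_library(path)
        assert [p.pattern for p in reloaded] == [p.pattern for p in library]
        assert [p.category for p in reloaded] == [p.category for p in library]


class TestInterpretability:
    def test_filters(self):
        keep = RegexPattern("A+P", "phrase-based")
        drop_no_attr = RegexPattern("PC", "phrase-based")
        drop_lab = RegexPattern("LN", "logic-based")
        kept = filter_interpretable([keep, drop_no_attr, drop_lab])
        assert kept == [keep]


class TestEnrichment:
    def test_gap_example_adds_conjunction_pattern(self, lexicon, schema, lab_kb):
        library = PatternLibrary([RegexPattern("A+P", "phrase-based", provenance="builtin")])
        text = "没有出现发热, 乏力"
        gold = [
            ph.PhenoSSUInstance(
                phenotype="fever",
                phenotype_span=(4, 6),
                attributes={"assertion": ("absent", (0, 4))},
            ),
            ph.PhenoSSUInstance(
                phenotype="fatigue",
                phenotype_span=(8, 10),
                attributes={"assertion": ("absent", (0, 4))},
            ),
        ]
        library2, report = ph.enrich(library, [(text, gold)], lexicon, lab_kb, schema)
        added = {a["pattern"] for a in report["added"]}
        assert "A+P(CP)+" in added
        new = next(p for p in library2 if p.pattern == "A+P(CP)+")
        assert new.provenance == "enriched" and new.review_flag

    def test_fixed_point(self, lexicon, schema, lab_kb, library, small_corpus):
        docs = [(d.text, d.instances) for d in small_corpus]
        lib1, rep1 = ph.enrich(library, docs, lexicon, lab_kb, schema)
        assert rep1["added"] == []
        lib2, rep2 = ph.enrich(lib1, docs, lexicon, lab_kb, schema)
        assert rep2["added"] == []
        assert lib1.pattern_set() == lib2.pattern_set()

    def test_unencodable_span_reported(self, schema, lab_kb):
        lexicon = ph.Lexicon([ph.LexiconEntry("疼痛", "P", "pain")])
        library = ph.builtin_library()
        gold = [
            ph.PhenoSSUInstance(
                phenotype="mystery",
                phenotype_span=(0, 2),
                attributes={"assertion": ("present", None)},
            )
        ]
        _, report = ph.enrich(library, [("这里没有词", gold)], lexicon, lab_kb, schema)
        assert report["unencodable"]


class TestLibraryOrder:
    def test_priority_puts_structured_patterns_first(self, library):
        order = [p.pattern for p in library]
        assert order.index("A+P(CP)+") == 0
        assert order.index("A*PC*A+") < order.index("AP+")
        assert order.index("S*LNU") < order.index("S*LR")
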