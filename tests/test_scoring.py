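"""Transcript scoring: content units, lexical categories, length measures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pdmci.registry import default_registry
from pdmci.scoring import (
    count_content_units,
    count_syllables,
    extract_language_features,
    lexical_counts,
    length_measures,
    match_content_units,
)
from pdmci.transcripts import Transcript

from conftest import brute_force_content_counts, make_transcript


class TestContentUnits:
    def test_repeats_sides_and_distinct(self, toy_lexicon):
        t = make_transcript("the dog and the dog and the sink")
        assert count_content_units(t, toy_lexicon, "any", "any", False) == 3
        assert count_content_units(t, toy_lexicon, "any", "any", True) == 2
        assert count_content_units(t, toy_lexicon, "any", "left", False) == 2
        assert count_content_units(t, toy_lexicon, "any", "left", True) == 1
        assert count_content_units(t, toy_lexicon, "any", "right", False) == 1

    def test_side_semantics(self, toy_lexicon):
        t = make_transcript("dog sink kitchen")
        assert count_content_units(t, toy_lexicon, "any", "left", False) == 1
        assert count_content_units(t, toy_lexicon, "any", "right", False) == 1
        assert count_content_units(t, toy_lexicon, "any", "both", False) == 1

    def test_relatedness_filter(self, toy_lexicon):
        t = make_transcript("dog garden garden")
        assert count_content_units(t, toy_lexicon, "related", "any", False) == 1
        assert count_content_units(t, toy_lexicon, "any", "any", False) == 3

    def test_longest_match_first(self, toy_lexicon):
        # "cookie jar" is one jar mention, not jar + anything else
        t = make_transcript("the cookie jar fell")
        assert count_content_units(t, toy_lexicon, "any", "any", False) == 1
        assert match_content_units(t, toy_lexicon)[0].unit_id == "jar"

    def test_case_insensitive(self, toy_lexicon):
        lower = make_transcript("the dog and the sink")
        upper = Transcript.from_tuples(
            "p2", [("The", "DT", 0), ("DOG", "NN", 0), ("and", "CC", 0),
                   ("the", "DT", 0), ("Sink", "NN", 0)])
        for filt in ("left", "right", "any"):
            assert (count_content_units(lower, toy_lexicon, "any", filt, False)
                    == count_content_units(upper, toy_lexicon, "any", filt, False))

    def test_empty_transcript_scores_zero(self, toy_lexicon):
        t = Transcript("empty", [])
        assert count_content_units(t, toy_lexicon, "related", "any", True) == 0

    def test_matches_brute_force_scanner(self, toy_lexicon):
        """Randomized transcripts agree with an independent token-window oracle."""
        vocab = ["dog", "sink", "kitchen", "jar", "cookie", "garden", "the",
                 "and", "a", "very", "big"]
        rng = np.random.default_rng(42)
        for _ in range(300):
            words = [vocab[k] for k in rng.integers(0, len(vocab),
                                                    rng.integers(0, 25))]
            t = make_transcript(" ".join(words))
            oracle = brute_force_content_counts([w.lower() for w in words],
                                                toy_lexicon)
            assert [u.unit_id for u in match_content_units(t, toy_lexicon)] == [
                u.unit_id for u in oracle]

    @given(st.lists(st.sampled_from(["dog", "sink", "kitchen", "garden", "the",
                                     "and"]), max_size=20))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_added_mention(self, words):
        from pdmci.lexicon import ContentUnit, ContentUnitLexicon

        lex = ContentUnitLexicon([
            ContentUnit("dog", ("dog",), "related", "left"),
            ContentUnit("sink", ("sink",), "related", "right"),
            ContentUnit("kitchen", ("kitchen",), "related", "both"),
            ContentUnit("garden", ("garden",), "unrelated", "right"),
        ])
        t = make_transcript(" ".join(words)) if words else Transcript("p", [])
        t_plus = make_transcript(" ".join(words + ["dog"]))
        seen_dog = "dog" in words
        for rel in ("related", "any"):
            base = count_content_units(t, lex, rel, "any", False)
            assert count_content_units(t_plus, lex, rel, "any", False) == base + 1
            base_d = count_content_units(t, lex, rel, "any", True)
            expected = base_d if seen_dog else base_d + 1
            assert count_content_units(t_plus, lex, rel, "any", True) == expected

    def test_filter_algebra(self, toy_lexicon):
        t = make_transcript("dog dog sink kitchen garden jar the dog")
        for loc in ("left", "right", "both", "any"):
            total = count_content_units(t, toy_lexicon, "any", loc, False)
            rel = count_content_units(t, toy_lexicon, "related", loc, False)
            mentions = [u for u in match_content_units(t, toy_lexicon)
                        if loc in ("any", u.location)]
            unrel = sum(1 for u in mentions if u.relatedness == "unrelated")
            assert rel + unrel == total
            assert count_content_units(t, toy_lexicon, "any", loc, True) <= total
        # location partition is complete: LEFT + RIGHT + Both Sides = ALL
        parts = [count_content_units(t, toy_lexicon, "any", loc, False)
                 for loc in ("left", "right", "both")]
        assert sum(parts) == count_content_units(t, toy_lexicon, "any", "any", False)


class TestLexicalCounts:
    def test_hand_tagged_sentence(self):
        t = Transcript.from_tuples("p", [
            ("the", "DT", 0), ("boy", "NN", 0), ("could", "MD", 0),
            ("reach", "VB", 0), ("a", "DT", 0), ("cookie", "NN", 0)])
        counts = lexical_counts(t)
        assert counts["modals"] == 1
        assert counts["indefinite articles"] == 1
        assert counts["nouns"] == 2
        assert counts["prepositions"] == 0

    def test_empty_transcript(self):
        counts = lexical_counts(Transcript("p", []))
        assert all(v == 0 for v in counts.values())

    def test_expected_categories_present(self):
        counts = lexical_counts(Transcript("p", []))
        for cat in ("modals", "prepositions", "indefinite articles", "nouns",
                    "function words", "pro-sentences"):
            assert cat in counts


class TestLengthMeasures:
    def test_empty_transcript_all_zero(self):
        m = length_measures(Transcript("p", []))
        assert all(v == 0 for v in m.values())

    def test_words_and_sentences(self):
        t = make_transcript("the dog barks . the boy runs .")
        m = length_measures(t)
        assert m["words"] == 6
        assert m["sentences"] == 2

    def test_syllable_heuristic_against_hand_counts(self):
        hand = {"cat": 1, "dog": 1, "water": 2, "cookie": 2, "window": 2,
                "mother": 2, "little": 2, "running": 2, "over": 2, "banana": 3,
                "kitchen": 2, "curtain": 2, "boy": 1, "girl": 1, "sink": 1,
                "theme": 1, "stool": 1, "plate": 1, "dish": 1, "family": 3}
        agree = sum(count_syllables(w) == s for w, s in hand.items())
        assert agree / len(hand) >= 0.9

    def test_complete_sentence_rule(self):
        # finite verb + nominal -> complete; bare NP -> not
        t = Transcript.from_tuples("p", [
            ("the", "DT", 0), ("dog", "NN", 0), ("barks", "VBZ", 0),
            ("the", "DT", 1), ("sink", "NN", 1)])
        assert length_measures(t)["complete sentences"] == 1


class TestExtraction:
    def test_all_registry_features_emitted(self, toy_lexicon):
        reg = default_registry()
        t = make_transcript("the dog and the sink .")
        vec = extract_language_features(t, toy_lexicon, reg)
        assert set(vec) == set(reg.language)
        assert "Count of DISTINCT RELATED content units" in vec
        assert all(v >= 0 for k, v in vec.items() if k.startswith("Count"))

    def test_unknown_feature_raises_with_name(self, toy_lexicon):
        from pdmci.registry import FeatureRegistry

        reg = FeatureRegistry.from_names(acoustic=["A1"], language=["Nonsense"])
        with pytest.raises(KeyError, match="Nonsense"):
            extract_language_features(make_transcript("dog"), toy_lexicon, reg)

    def test_sentence_permutation_leaves_bag_counts(self, toy_lexicon):
        reg = default_registry()
        t1 = make_transcript("the dog barks . a sink overflows .")
        t2 = make_transcript("a sink overflows . the dog barks .")
        v1 = extract_language_features(t1, toy_lexicon, reg)
        v2 = extract_language_features(t2, toy_lexicon, reg)
        for name in ("Count of ALL content units", "Count of words",
                     "Count of sentences", "Count of nouns",
                     "Count of indefinite articles", "Count of Syllables"):
            assert v1[name] == v2[name]
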