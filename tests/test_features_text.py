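"""Task, semantic and syntactic feature families."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speechmarkers import (iu_summary_features, lexical_stats, match_mentions,
                           mattr, parse_chat, per_iu_features, pos_stats,
                           sentence_stats, spatial_features, ttr, word_count)
from speechmarkers.features_text import (dependency_stats,
                                         extract_text_features)
from speechmarkers.ingest import Mention
from speechmarkers.tagging import LexiconTagger, TaggedToken
from speechmarkers.vectors import is_missing


def mentions_of(transcript, lexicon):
    return match_mentions(transcript, lexicon)


class TestPerIU:
    def test_worked_example_counts(self, example_transcript, en_lexicon):
        fv = per_iu_features(mentions_of(example_transcript, en_lexicon),
                             en_lexicon)
        assert fv["boy_count"] == 3
        assert fv["boy_ratio"] == pytest.approx(0.6)
        assert fv["boy_mentioned"] == 1
        assert fv["window_mentioned"] == 0
        assert len(fv) == 48

    def test_empty_mentions_all_zero(self, en_lexicon):
        fv = per_iu_features([], en_lexicon)
        assert all(v == 0 for v in fv.values.values())

    def test_single_mention_normalizes(self, en_lexicon):
        fv = per_iu_features([Mention(0, "jar", "jar")], en_lexicon)
        assert fv["jar_ratio"] == 1.0
        total = sum(fv[f"{n}_ratio"] for n in
                    (e.name for e in en_lexicon.ius))
        assert total == pytest.approx(1.0)

    def test_ratios_sum_to_one_with_mentions(self, example_transcript,
                                             en_lexicon):
        fv = per_iu_features(mentions_of(example_transcript, en_lexicon),
                             en_lexicon)
        total = sum(fv[f"{e.name}_ratio"] for e in en_lexicon.ius)
        assert total == pytest.approx(1.0)


class TestSpatial:
    def test_half_switches_counts_adjacent_changes(self, en_lexicon):
        # boy(left), girl(left), woman(right), cookie(left): L,L,R,L -> 2
        mentions = [Mention(0, "boy", "boy"), Mention(1, "girl", "girl"),
                    Mention(2, "woman", "woman"),
                    Mention(3, "cookie", "cookie")]
        fv = spatial_features(mentions, en_lexicon, "halves", n_words=10)
        assert fv["half_switches"] == 2

    def test_no_mentions_all_zero(self, en_lexicon):
        for division in ("halves", "quadrants", "stripes"):
            fv = spatial_features([], en_lexicon, division, n_words=10)
            assert all(v == 0 for v in fv.values.values())

    def test_full_coverage_saturates(self, en_lexicon):
        mentions = [Mention(i, sorted(e.keywords)[0], e.name)
                    for i, e in enumerate(en_lexicon.ius)]
        for division in ("halves", "quadrants", "stripes"):
            fv = spatial_features(mentions, en_lexicon, division, n_words=32)
            pct = [v for k, v in fv.values.items()
                   if k.endswith("percent_uttered")]
            assert all(v == pytest.approx(1.0) for v in pct)


class TestIUSummary:
    def test_worked_example_matches_published_values(
            self, example_transcript, en_lexicon):
        mentions = mentions_of(example_transcript, en_lexicon)
        fv = iu_summary_features(mentions, word_count(example_transcript),
                                 15.0, en_lexicon)
        assert fv["num_unique_IU"] == 3
        assert fv["num_unique_keywords"] == 4
        assert fv["num_total_keywords"] == 5
        assert round(fv["unique_IU_density"], 4) == 0.1667
        assert round(fv["total_IU_density"], 4) == 0.2778
        assert round(fv["keyword_to_non_keyword_ratio"], 4) == 0.3846
        assert fv["unique_keyword_density"] == pytest.approx(4 / 18)
        assert fv["percentage_of_keywords_mentioned"] == 0.1875
        assert fv["keyword_TTR"] == pytest.approx(0.8)
        assert round(fv["total_IU_efficiency"], 2) == 0.33
        assert fv["unique_IU_efficiency"] == pytest.approx(0.2)

    def test_no_mentions(self, en_lexicon):
        fv = iu_summary_features([], 10, None, en_lexicon)
        assert fv["num_total_keywords"] == 0
        assert fv["total_IU_density"] == 0
        assert fv["keyword_to_non_keyword_ratio"] == 0
        assert is_missing(fv["keyword_TTR"])
        assert is_missing(fv["total_IU_efficiency"])

    def test_distinct_keywords_ttr_one(self, en_lexicon):
        mentions = [Mention(0, "boy", "boy"), Mention(1, "girl", "girl")]
        fv = iu_summary_features(mentions, 10, 5.0, en_lexicon)
        assert fv["keyword_TTR"] == 1.0

    def test_all_keywords_warns_missing_ratio(self, en_lexicon):
        mentions = [Mention(0, "boy", "boy"), Mention(1, "girl", "girl")]
        with pytest.warns(UserWarning):
            fv = iu_summary_features(mentions, 2, 5.0, en_lexicon)
        assert is_missing(fv["keyword_to_non_keyword_ratio"])

    @settings(max_examples=40, deadline=None)
    @given(n_mentions=st.integers(0, 8), n_words=st.integers(9, 60))
    def test_density_ratio_identity(self, en_lexicon, n_mentions, n_words):
        """keyword_to_non_keyword_ratio == d/(1-d) with d = total density."""
        mentions = [Mention(i, "boy", "boy") for i in range(n_mentions)]
        fv = iu_summary_features(mentions, n_words, None, en_lexicon)
        d = fv["total_IU_density"]
        assert fv["keyword_to_non_keyword_ratio"] == \
            pytest.approx(d / (1 - d))


class TestLexicalStats:
    def test_direct_arithmetic(self, en_lexicon):
        t = parse_chat("*PAR:\ta cat .")
        fv = lexical_stats(t, [], {"a": 0.02, "cat": 0.001})
        assert fv["mean_word_frequency_all"] == pytest.approx(0.0105)
        assert fv["max_word_frequency_all"] == pytest.approx(0.02)
        assert fv["mean_word_length_all"] == pytest.approx(2.0)

    def test_lengths(self):
        t = parse_chat("*PAR:\tcat mouse .")  # lengths 3, 5
        fv = lexical_stats(t, [], {})
        assert fv["mean_word_length_all"] == 4
        assert fv["max_word_length_all"] == 5

    def test_no_keywords_missing(self):
        t = parse_chat("*PAR:\tcat .")
        fv = lexical_stats(t, [], {})
        assert is_missing(fv["mean_word_frequency_IU"])
        assert is_missing(fv["max_word_length_IU"])


class TestDiversity:
    def test_ttr_examples(self):
        assert ttr(parse_chat("*PAR:\t" + " ".join(["word"] * 10) + " .")) \
            == pytest.approx(0.1)
        assert ttr(parse_chat("*PAR:\ta b c d e f g .")) == 1.0

    def test_ttr_worked_example(self, example_transcript):
        assert ttr(example_transcript) == pytest.approx(11 / 18)

    def test_mattr_examples(self):
        assert mattr(parse_chat("*PAR:\t" + " ".join(["w"] * 10) + " .")) \
            == pytest.approx(0.1)
        twelve = " ".join(f"w{i}" for i in range(12))
        assert mattr(parse_chat("*PAR:\t" + twelve + " .")) == 1.0

    def test_mattr_two_window_enumeration(self):
        # a b a b a b a b a b a: both 10-token windows hold 2 types
        t = parse_chat("*PAR:\t" + " ".join("ab" * 5 + "a") + " .")
        assert mattr(t) == pytest.approx(0.2)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.sampled_from("abcde"), min_size=1, max_size=25))
    def test_mattr_full_window_equals_ttr(self, letters):
        t = parse_chat("*PAR:\t" + " ".join(letters) + " .")
        assert mattr(t, window=word_count(t)) == pytest.approx(ttr(t))


class TestSentenceStats:
    def test_worked_example(self, example_transcript):
        fv = sentence_stats(example_transcript)
        assert fv["number_of_sentences"] == 4
        assert fv["word_count"] == 18
        assert fv["mean_words_per_sentence"] == pytest.approx(4.5)

    def test_single_word(self):
        fv = sentence_stats(parse_chat("*PAR:\tyes ."))
        assert fv["mean_words_per_sentence"] == 1.0


class TestPosStats:
    def test_basic_counts_and_ratios(self):
        tagged = [[TaggedToken("the", "DET", 1), TaggedToken("boy", "NOUN", 1),
                   TaggedToken("is", "AUX", 1),
                   TaggedToken("running", "VERB", 0)]]
        fv = pos_stats(tagged)
        assert fv["NOUN_count"] == 1
        assert fv["NOUN_ratio"] == pytest.approx(0.25)
        assert fv["open_closed_ratio"] == pytest.approx(1.0)

    def test_zero_denominator_missing(self):
        tagged = [[TaggedToken("he", "PRON", 0)]]
        fv = pos_stats(tagged)
        assert is_missing(fv["pronoun_noun_ratio"])

    def test_punct_only(self):
        tagged = [[TaggedToken(".", "PUNCT", 0)]]
        fv = pos_stats(tagged)
        assert fv["PUNCT_count"] == 1
        assert fv["PUNCT_ratio"] == 1.0
        assert is_missing(fv["NOUN_ratio"])

    def test_counts_sum_to_word_count(self, example_transcript):
        tagger = LexiconTagger("en")
        tagged = tagger(example_transcript)
        fv = pos_stats(tagged)
        word_tags = [t for t in
                     ("ADJ ADP ADV AUX CCONJ DET INTJ NOUN NUM PART PRON "
                      "PROPN SCONJ SYM VERB X").split()]
        total = sum(fv[f"{t}_count"] for t in word_tags)
        assert total == word_count(example_transcript)

    def test_unknown_tag_raises(self):
        with pytest.raises(ValueError, match="NOUNX"):
            TaggedToken("x", "NOUNX", 0)


class TestDependencyStats:
    def test_adjacent_dependent(self):
        tagged = [[TaggedToken("boy", "NOUN", 1),
                   TaggedToken("runs", "VERB", 0)]]
        fv = dependency_stats(tagged)
        assert fv["mean_dependency_length"] == 1
        assert fv["median_dependency_length"] == 1
        assert fv["max_dependency_length"] == 1

    def test_chain_enumeration(self):
        tagged = [[TaggedToken("a", "DET", 0), TaggedToken("b", "NOUN", -1),
                   TaggedToken("c", "NOUN", -1)]]
        fv = dependency_stats(tagged)
        assert fv["mean_dependency_length"] == pytest.approx(1.0)

    def test_root_only_excluded(self):
        with pytest.warns(UserWarning):
            fv = dependency_stats([[TaggedToken("yes", "INTJ", 0)]])
        assert is_missing(fv["mean_dependency_length"])


class TestCombined:
    def test_registry_families_and_punctuation_invariance(
            self, example_transcript, en_lexicon):
        fv = extract_text_features(example_transcript, en_lexicon,
                                   duration_s=15.0)
        subs = set(fv.registry.values())
        assert subs == {"task", "semantic", "syntactic"}
        # semantic summary features ignore punctuation tokens
        no_punct = parse_chat(
            "*PAR:\tThere is a boy The boy is a brother He is stealing a "
            "cookie The sister is watching .")
        fv2 = extract_text_features(no_punct, en_lexicon, duration_s=15.0)
        for name, sub in fv.registry.items():
            if sub == "semantic" and "word" not in name:
                if not (is_missing(fv[name]) or is_missing(fv2[name])):
                    if name in ("MATTR",):
                        continue
                    assert fv[name] == pytest.approx(fv2[name]), name
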