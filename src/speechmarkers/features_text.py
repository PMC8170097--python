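"""Task-specific, semantic and syntactic features from a transcript.

Three families are computed from the participant's picture description:

* **task** — per-information-unit mention indicators/counts/ratios and
  spatial coverage of the picture under three division schemes; these
  measure task performance rather than language ability.
* **semantic** — information-unit summaries (density, efficiency, coverage
  of the 16-IU inventory), lexical frequency/length statistics, and lexical
  diversity (TTR and its moving-average variant MATTR).
* **syntactic** — sentence statistics, Universal-POS tag counts and ratios,
  and dependency-length summaries from a tagging backend.
"""

from __future__ import annotations

import csv
import math
import warnings
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .ingest import (IU_NAMES, IULexicon, Mention, Transcript, word_count)
from .tagging import (CLOSED_CLASS, OPEN_CLASS, TaggedToken, Tagger,
                      UPOS_TAGS, get_tagger)
from .vectors import MISSING, FeatureVector

__all__ = [
    "per_iu_features", "spatial_features", "iu_summary_features",
    "lexical_stats", "ttr", "mattr", "sentence_stats", "pos_stats",
    "dependency_stats", "load_frequency_table", "extract_text_features",
]


# ---------------------------------------------------------------------------
# Task-specific family

def per_iu_features(mentions: Sequence[Mention],
                    lexicon: IULexicon) -> FeatureVector:
    """Per-IU mention indicator, count, and share of all mentions (48)."""
    fv = FeatureVector()
    counts = {name: 0 for name in IU_NAMES}
    for m in mentions:
        counts[m.iu_name] += 1
    total = sum(counts.values())
    for name in IU_NAMES:
        c = counts[name]
        fv.add(f"{name}_mentioned", 1.0 if c else 0.0, "task")
        fv.add(f"{name}_count", float(c), "task")
        fv.add(f"{name}_ratio", c / total if total else 0.0, "task")
    return fv


def _region_key(region: str) -> str:
    return region.replace("-", "_")


def spatial_features(mentions: Sequence[Mention], lexicon: IULexicon,
                     division: str, n_words: int) -> FeatureVector:
    """Keyword coverage per picture region (halves/quadrants/stripes).

    Per region: keyword token count, keyword type-token ratio,
    keyword-to-word ratio, and the fraction of the region's assigned IUs
    that were mentioned.  For halves additionally the number of switches
    between sides in the mention order (a proxy for scanning strategy).
    """
    fv = FeatureVector()
    regions = lexicon.regions(division)
    per_region_tokens: dict[str, list[str]] = {r: [] for r in regions}
    per_region_ius: dict[str, set[str]] = {r: set() for r in regions}
    seq: list[str] = []
    for m in mentions:
        r = lexicon.region_of(m.iu_name, division)
        per_region_tokens[r].append(m.keyword)
        per_region_ius[r].add(m.iu_name)
        seq.append(r)
    assigned: dict[str, int] = {r: 0 for r in regions}
    for e in lexicon.ius:
        assigned[lexicon.region_of(e.name, division)] += 1
    for r in regions:
        toks = per_region_tokens[r]
        key = _region_key(r)
        fv.add(f"{key}_word_count", float(len(toks)), "task")
        fv.add(f"{key}_ttr", len(set(toks)) / len(toks) if toks else 0.0,
               "task")
        fv.add(f"{key}_keyword_to_word_ratio",
               len(toks) / n_words if n_words else 0.0, "task")
        fv.add(f"{key}_percent_uttered",
               len(per_region_ius[r]) / assigned[r] if assigned[r] else 0.0,
               "task")
    if division == "halves":
        switches = sum(1 for a, b in zip(seq, seq[1:]) if a != b)
        fv.add("half_switches", float(switches), "task")
    return fv


# ---------------------------------------------------------------------------
# Semantic family

def iu_summary_features(mentions: Sequence[Mention], n_words: int,
                        duration_s: Optional[float],
                        lexicon: IULexicon) -> FeatureVector:
    """Information-unit summary features.

    ``num_total_keywords`` counts every keyword mention; densities divide
    by the transcript word count; efficiencies divide by the response
    duration in seconds (missing when no duration is known);
    ``percentage_of_keywords_mentioned`` is coverage of the 16-IU
    inventory.
    """
    fv = FeatureVector()
    unique_ius = {m.iu_name for m in mentions}
    unique_kws = {m.keyword for m in mentions}
    n_total = len(mentions)
    n_iu = len(unique_ius)
    n_kw = len(unique_kws)
    fv.add("num_unique_IU", float(n_iu), "semantic")
    fv.add("num_unique_keywords", float(n_kw), "semantic")
    fv.add("num_total_keywords", float(n_total), "semantic")
    fv.add("unique_IU_density", n_iu / n_words if n_words else MISSING,
           "semantic")
    fv.add("total_IU_density", n_total / n_words if n_words else MISSING,
           "semantic")
    if n_words > n_total:
        k2nk = n_total / (n_words - n_total)
    elif n_total == 0:
        k2nk = 0.0
    else:
        warnings.warn("every word is a keyword; keyword_to_non_keyword_ratio "
                      "undefined", stacklevel=2)
        k2nk = MISSING
    fv.add("keyword_to_non_keyword_ratio", k2nk, "semantic")
    fv.add("unique_keyword_density", n_kw / n_words if n_words else MISSING,
           "semantic")
    fv.add("percentage_of_keywords_mentioned", n_iu / len(IU_NAMES),
           "semantic")
    fv.add("keyword_TTR", n_kw / n_total if n_total else MISSING, "semantic")
    if duration_s and duration_s > 0:
        fv.add("total_IU_efficiency", n_total / duration_s, "semantic")
        fv.add("unique_IU_efficiency", n_iu / duration_s, "semantic")
    else:
        fv.add("total_IU_efficiency", MISSING, "semantic")
        fv.add("unique_IU_efficiency", MISSING, "semantic")
    return fv


def load_frequency_table(language: str = "en",
                         path: Optional[str | Path] = None) -> dict[str, float]:
    """Word -> relative frequency lookup (packaged per-language table).

    Out-of-vocabulary words look up as 0.  An external resource can be
    supplied as a two-column CSV (word, frequency).
    """
    if path is None:
        res = resources.files("speechmarkers.data") / f"wordfreq_{language}.csv"
        with resources.as_file(res) as p:
            path = Path(p)
    table: dict[str, float] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            table[row["word"].lower()] = float(row["frequency"])
    return table


def _stats_triple(fv: FeatureVector, prefix: str, values: Sequence[float],
                  subgroup: str = "semantic") -> None:
    if values:
        arr = np.asarray(values, dtype=float)
        fv.add(f"mean_{prefix}", float(arr.mean()), subgroup)
        fv.add(f"median_{prefix}", float(np.median(arr)), subgroup)
        fv.add(f"max_{prefix}", float(arr.max()), subgroup)
    else:
        fv.add(f"mean_{prefix}", MISSING, subgroup)
        fv.add(f"median_{prefix}", MISSING, subgroup)
        fv.add(f"max_{prefix}", MISSING, subgroup)


def lexical_stats(transcript: Transcript, mentions: Sequence[Mention],
                  freq: Mapping[str, float]) -> FeatureVector:
    """Word frequency and word length statistics, for all words and for
    mentioned keywords (12 features)."""
    fv = FeatureVector()
    words = [w.lower() for w in transcript.words()]
    kws = [m.keyword for m in mentions]
    _stats_triple(fv, "word_frequency_all", [freq.get(w, 0.0) for w in words])
    _stats_triple(fv, "word_frequency_IU", [freq.get(k, 0.0) for k in kws])
    _stats_triple(fv, "word_length_all", [float(len(w)) for w in words])
    _stats_triple(fv, "word_length_IU", [float(len(k)) for k in kws])
    return fv


def ttr(transcript: Transcript) -> float:
    """Type-token ratio: unique words / total words (case-folded)."""
    words = [w.lower() for w in transcript.words()]
    if not words:
        return MISSING
    return len(set(words)) / len(words)


def mattr(transcript: Transcript, window: int = 10) -> float:
    """Moving-average TTR over a fixed-size sliding window of word tokens.

    The TTR of words 1..w, then 2..w+1, ... is averaged, reducing the
    text-length dependence of plain TTR.  Texts shorter than the window
    fall back to the whole-text TTR.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    words = [w.lower() for w in transcript.words()]
    if not words:
        return MISSING
    if len(words) < window:
        return len(set(words)) / len(words)
    ratios = [len(set(words[i:i + window])) / window
              for i in range(len(words) - window + 1)]
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# Syntactic family

def sentence_stats(transcript: Transcript) -> FeatureVector:
    """Sentence count, word count and mean words per sentence."""
    fv = FeatureVector()
    n_sent = transcript.n_utterances
    n_words = word_count(transcript)
    if n_sent == 0:
        fv.add("number_of_sentences", MISSING, "syntactic")
        fv.add("word_count", MISSING, "syntactic")
        fv.add("mean_words_per_sentence", MISSING, "syntactic")
        return fv
    fv.add("number_of_sentences", float(n_sent), "syntactic")
    fv.add("word_count", float(n_words), "syntactic")
    fv.add("mean_words_per_sentence", n_words / n_sent, "syntactic")
    return fv


def pos_stats(tagged: Sequence[Sequence[TaggedToken]]) -> FeatureVector:
    """Per-UPOS-tag counts and ratios plus four class ratios.

    Ratio denominators are the word count (punctuation excluded), except
    ``PUNCT_ratio`` whose denominator is all tokens.  Zero denominators
    yield missing values.
    """
    fv = FeatureVector()
    counts = {t: 0 for t in UPOS_TAGS}
    n_tokens = 0
    for utt in tagged:
        for tok in utt:
            if tok.upos not in counts:
                raise ValueError(f"unknown UPOS tag {tok.upos!r}")
            counts[tok.upos] += 1
            n_tokens += 1
    n_words = n_tokens - counts["PUNCT"]
    for tag in UPOS_TAGS:
        fv.add(f"{tag}_count", float(counts[tag]), "syntactic")
        if tag == "PUNCT":
            ratio = counts[tag] / n_tokens if n_tokens else MISSING
        else:
            ratio = counts[tag] / n_words if n_words else MISSING
        fv.add(f"{tag}_ratio", ratio, "syntactic")

    def _ratio(a: str, b: str) -> float:
        return counts[a] / counts[b] if counts[b] else MISSING

    fv.add("noun_verb_ratio", _ratio("NOUN", "VERB"), "syntactic")
    fv.add("pronoun_noun_ratio", _ratio("PRON", "NOUN"), "syntactic")
    fv.add("determiner_noun_ratio", _ratio("DET", "NOUN"), "syntactic")
    n_open = sum(counts[t] for t in OPEN_CLASS)
    n_closed = sum(counts[t] for t in CLOSED_CLASS)
    fv.add("open_closed_ratio", n_open / n_closed if n_closed else MISSING,
           "syntactic")
    return fv


def dependency_stats(tagged: Sequence[Sequence[TaggedToken]]) -> FeatureVector:
    """Mean/median/max absolute distance to the syntactic head over all
    non-root tokens (punctuation arcs excluded)."""
    fv = FeatureVector()
    lengths = [abs(tok.head_offset) for utt in tagged for tok in utt
               if tok.head_offset != 0 and tok.upos != "PUNCT"]
    if lengths:
        arr = np.asarray(lengths, dtype=float)
        fv.add("mean_dependency_length", float(arr.mean()), "syntactic")
        fv.add("median_dependency_length", float(np.median(arr)), "syntactic")
        fv.add("max_dependency_length", float(arr.max()), "syntactic")
    else:
        warnings.warn("no dependency arcs available", stacklevel=2)
        fv.add("mean_dependency_length", MISSING, "syntactic")
        fv.add("median_dependency_length", MISSING, "syntactic")
        fv.add("max_dependency_length", MISSING, "syntactic")
    return fv


# ---------------------------------------------------------------------------
# Combined extraction

def extract_text_features(transcript: Transcript, lexicon: IULexicon,
                          duration_s: Optional[float] = None,
                          tagger: Optional[Tagger] = None,
                          freq: Optional[Mapping[str, float]] = None,
                          subject_id: str = "") -> FeatureVector:
    """All task, semantic and syntactic features for one transcript."""
    from .ingest import match_mentions

    if tagger is None:
        tagger = get_tagger(lexicon.language)
    if freq is None:
        freq = load_frequency_table(lexicon.language)
    mentions = match_mentions(transcript, lexicon)
    n_words = word_count(transcript)
    fv = FeatureVector(subject_id=subject_id)
    fv.merge(per_iu_features(mentions, lexicon))
    for division in ("halves", "quadrants", "stripes"):
        fv.merge(spatial_features(mentions, lexicon, division, n_words))
    fv.merge(iu_summary_features(mentions, n_words, duration_s, lexicon))
    fv.merge(lexical_stats(transcript, mentions, freq))
    sem = FeatureVector()
    sem.add("TTR", ttr(transcript), "semantic")
    sem.add("MATTR", mattr(transcript), "semantic")
    fv.merge(sem)
    fv.merge(sentence_stats(transcript))
    tagged = tagger(transcript)
    fv.merge(pos_stats(tagged))
    fv.merge(dependency_stats(tagged))
    return fv
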