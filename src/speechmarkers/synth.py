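"""Synthetic bilingual cohorts with known ground-truth group effects.

The clinical corpora this kind of analysis runs on are access-restricted,
so the generator builds Cookie-Theft-like cohorts whose *statistical*
structure mirrors what is reported for real AD vs. HC picture
descriptions, with every planted effect recorded in a ``GroundTruth`` map:

* semantic effects in both languages — the AD group mentions fewer
  information units (lower per-IU Bernoulli rate), uses the generic head
  noun instead of specific synonyms, and substitutes pronouns for repeated
  nouns (which also raises the pronoun ratio, a syntactic effect);
* group-dependent response duration (AD shorter, lognormal);
* demographics: age sampled per language and group, with the French cohort
  older and age-unbalanced;
* paralinguistic features drawn from language-specific Gaussians with
  standardized group shifts only for configured (feature, language) pairs —
  mostly language-specific, matching the reported weak cross-language
  overlap of acoustic features.

Transcripts are realized as templated CHAT-parseable sentences so the real
text extractors run on them end to end; no attempt is made at natural
discourse, only feature-level structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .features_audio import PARALINGUISTIC_FEATURES
from .ingest import IU_NAMES, SubjectRecord, Token, Transcript, load_lexicon

__all__ = ["SynthParams", "GroundTruth", "generate_cohort",
           "generate_paralinguistic_table", "cohort_to_chat"]

# verb phrases free of IU keywords, so templated sentences add exactly one
# keyword mention each
_VPS_EN = {
    "boy": "is reaching up", "girl": "is laughing", "woman": "is busy",
    "kitchen": "is messy", "exterior": "is visible", "cookie": "is sweet",
    "jar": "is open", "stool": "is wobbling", "sink": "is full",
    "plate": "is clean", "dishcloth": "is wet", "water": "is overflowing",
    "window": "is open", "cupboard": "is high", "dish": "is dry",
    "curtain": "is drawn",
}
_VPS_FR = {
    "boy": "monte", "girl": "regarde", "woman": "est occupée",
    "kitchen": "est pleine", "exterior": "est propre", "cookie": "tombe",
    "jar": "est ouvert", "stool": "vacille", "sink": "est plein",
    "plate": "est propre", "dishcloth": "est mouillé", "water": "déborde",
    "window": "est ouverte", "cupboard": "est haut", "dish": "est propre",
    "curtain": "tombe",
}
_FR_FEMININE = {
    "fille", "sœur", "soeur", "fillette", "femme", "mère", "maman", "dame",
    "épouse", "cuisine", "fenêtre", "assiette", "vaisselle", "tasse",
    "armoire", "étagère", "eau", "allée", "jarre", "boîte à biscuits",
}
# the generic name for each information unit; other synonyms count as
# "specific" lexical choices
_HEAD_KEYWORDS = {
    "en": {iu: iu for iu in IU_NAMES} | {"exterior": "outside"},
    "fr": {"boy": "garçon", "girl": "fille", "woman": "femme",
           "kitchen": "cuisine", "exterior": "dehors", "cookie": "biscuit",
           "jar": "bocal", "stool": "tabouret", "sink": "évier",
           "plate": "assiette", "dishcloth": "torchon", "water": "eau",
           "window": "fenêtre", "cupboard": "placard", "dish": "vaisselle",
           "curtain": "rideau"},
}

_PRONOUN = {"en": {"animate": "he", "inanimate": "it"},
            "fr": {"masc": "il", "fem": "elle"}}
_ANIMATE_IUS = {"boy", "girl", "woman"}
_FILLER = {"en": "uh", "fr": "euh"}


@dataclass
class SynthParams:
    """Generator settings; the defaults are the study conditions.

    Probabilities are per group as ``{"HC": x, "AD": y}``; effects on
    paralinguistic features are ``(feature_name, languages, standardized
    shift)`` triples, where the shift is added to the AD group mean in
    units of the feature's within-group standard deviation.
    """

    n_per_group_per_language: int = 50
    iu_mention_prob: dict = field(
        default_factory=lambda: {"HC": 0.7, "AD": 0.4})
    specific_keyword_prob: dict = field(
        default_factory=lambda: {"HC": 0.5, "AD": 0.2})
    pronoun_substitution_prob: dict = field(
        default_factory=lambda: {"HC": 0.1, "AD": 0.35})
    filler_rate: dict = field(
        default_factory=lambda: {"HC": 0.05, "AD": 0.15})
    repeat_prob: dict = field(
        default_factory=lambda: {"HC": 0.45, "AD": 0.35})
    duration_lognormal: dict = field(
        default_factory=lambda: {"HC": (4.1, 0.45), "AD": (3.8, 0.5)})
    age_normal: dict = field(default_factory=lambda: {
        ("en", "HC"): (66.1, 6.5), ("en", "AD"): (66.8, 6.6),
        ("fr", "HC"): (75.4, 7.0), ("fr", "AD"): (81.6, 4.5)})
    paralinguistic_effects: tuple = (
        # (feature, languages with the effect, standardized AD shift)
        ("ratio_speaking", ("en", "fr"), -0.8),
        ("speech_rate", ("en", "fr"), -0.6),
        ("loudness_std", ("fr",), -0.9),
        ("f0_std", ("fr",), -0.7),
        ("energy_skewness", ("fr",), 0.7),
        ("mfcc1_mean", ("en",), -0.6),
        ("bandwidth_mean", ("en",), 0.5),
        ("mfcc4_kurtosis", ("fr",), 0.6),
    )
    languages: tuple = ("en", "fr")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group_per_language < 2:
            raise ValueError("need n >= 2 per group per language")
        for d in (self.iu_mention_prob, self.specific_keyword_prob,
                  self.pronoun_substitution_prob, self.filler_rate,
                  self.repeat_prob):
            for v in d.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError("probabilities must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted effects: feature -> (languages with an effect, sign of
    m_AD - m_HC, approximate standardized effect magnitude |d|).

    Magnitudes for text features are design values implied by the group
    parameter gaps (e.g. the IU mention-rate gap yields |d| near 2), not
    fitted numbers; ``min_effect`` filters let callers reason about
    strongly-planted effects only.
    """

    effects: dict[str, tuple[frozenset[str], int, float]] = field(
        default_factory=dict)

    def languages_of(self, feature: str) -> frozenset[str]:
        return self.effects.get(feature, (frozenset(), 0, 0.0))[0]

    def bilingual_features(self, min_effect: float = 0.0) -> set[str]:
        return {f for f, (langs, _, d) in self.effects.items()
                if langs == frozenset({"en", "fr"}) and d >= min_effect}

    def single_language_features(self, min_effect: float = 0.0) -> set[str]:
        return {f for f, (langs, _, d) in self.effects.items()
                if len(langs) == 1 and d >= min_effect}


def _sentence_tokens(language: str, keyword: str, iu: str,
                     as_pronoun: bool, rng: np.random.Generator,
                     filler_rate: float) -> list[Token]:
    toks: list[Token] = []
    if rng.random() < filler_rate:
        toks.append(Token(_FILLER[language]))
    if language == "en":
        vp = _VPS_EN[iu]
        if as_pronoun:
            head = (_PRONOUN["en"]["animate"] if iu in _ANIMATE_IUS
                    else _PRONOUN["en"]["inanimate"])
            words = [head] + vp.split()
        else:
            words = ["the"] + keyword.split() + vp.split()
    else:
        vp = _VPS_FR[iu]
        fem = keyword in _FR_FEMININE
        if as_pronoun:
            words = [_PRONOUN["fr"]["fem" if fem else "masc"]] + vp.split()
        else:
            art = "la" if fem else "le"
            if keyword[0] in "aeiouéèê":
                words = ["l'" + keyword.split()[0]] + keyword.split()[1:] \
                    + vp.split()
            else:
                words = [art] + keyword.split() + vp.split()
    toks.extend(Token(w) for w in words)
    toks.append(Token(".", is_word=False))
    return toks


def _subject_transcript(language: str, group: str, params: SynthParams,
                        rng: np.random.Generator,
                        lexicon) -> Transcript:
    p_mention = params.iu_mention_prob[group]
    p_specific = params.specific_keyword_prob[group]
    p_pronoun = params.pronoun_substitution_prob[group]
    p_repeat = params.repeat_prob[group]
    filler = params.filler_rate[group]
    utterances: list[list[Token]] = []
    entries = lexicon.entries
    for iu in IU_NAMES:
        if rng.random() >= p_mention:
            continue
        kws = sorted(entries[iu].keywords)
        head = _HEAD_KEYWORDS[language].get(iu, kws[0])
        # generic head noun vs. specific synonym mention
        specific = [k for k in kws if k != head]
        if specific and rng.random() < p_specific:
            kw = specific[int(rng.integers(len(specific)))]
        else:
            kw = head
        utterances.append(_sentence_tokens(language, kw, iu, False, rng,
                                           filler))
        if rng.random() < p_repeat:
            as_pronoun = rng.random() < p_pronoun
            utterances.append(_sentence_tokens(language, kw, iu, as_pronoun,
                                               rng, filler))
    if not utterances:
        # degenerate draw: guarantee a non-empty transcript
        utterances.append(_sentence_tokens(language, "kitchen" if
                                           language == "en" else "cuisine",
                                           "kitchen", False, rng, 0.0))
    return Transcript(utterances)


_BOTH = frozenset({"en", "fr"})

_TEXT_EFFECTS = {
    # features whose group difference follows from the generation process,
    # present in both languages by construction; magnitudes are design
    # values from the parameter gaps (the 0.7 vs 0.4 mention rate moves IU
    # counts by ~2 within-group SDs; unique_IU_efficiency is diluted
    # because the AD group also responds for less time)
    "num_unique_IU": (_BOTH, -1, 2.0),
    "num_unique_keywords": (_BOTH, -1, 2.0),
    "num_total_keywords": (_BOTH, -1, 2.0),
    "percentage_of_keywords_mentioned": (_BOTH, -1, 2.0),
    "word_count": (_BOTH, -1, 2.0),
    "PRON_ratio": (_BOTH, 1, 1.0),
    "keyword_TTR": (_BOTH, -1, 1.0),
    "unique_IU_efficiency": (_BOTH, -1, 0.5),
}


def generate_cohort(params: SynthParams
                    ) -> tuple[list[SubjectRecord], pd.Series, GroundTruth]:
    """Sample a bilingual HC/AD cohort of transcripts with metadata.

    Returns the subject records, a label series indexed by subject id, and
    the ground-truth effect map covering both the construction-implied text
    effects and the configured paralinguistic effects.
    """
    rng = np.random.default_rng(params.seed)
    records: list[SubjectRecord] = []
    lexicons = {lang: load_lexicon(language=lang)
                for lang in params.languages}
    for lang in params.languages:
        for group in ("HC", "AD"):
            mu_a, sd_a = params.age_normal[(lang, group)]
            mu_d, sd_d = params.duration_lognormal[group]
            for k in range(params.n_per_group_per_language):
                sid = f"{lang}_{group}_{k:03d}"
                transcript = _subject_transcript(lang, group, params, rng,
                                                 lexicons[lang])
                duration = float(np.exp(rng.normal(mu_d, sd_d)))
                age = float(rng.normal(mu_a, sd_a))
                records.append(SubjectRecord(
                    subject_id=sid, language=lang, group=group,
                    transcript=transcript, age=age, duration_s=duration))
    labels = pd.Series({r.subject_id: r.group for r in records})
    gt = GroundTruth(effects=dict(_TEXT_EFFECTS))
    for name, langs, shift in params.paralinguistic_effects:
        gt.effects[name] = (frozenset(langs), int(np.sign(shift)),
                            abs(float(shift)))
    return records, labels, gt


def generate_paralinguistic_table(params: SynthParams,
                                  subjects: Sequence[SubjectRecord],
                                  ground_truth: Optional[GroundTruth] = None
                                  ) -> pd.DataFrame:
    """Gaussian paralinguistic feature rows standing in for audio.

    Each registered paralinguistic feature is drawn from a
    language-specific unit Gaussian; the configured standardized group
    shift is added to the AD mean only for (feature, language) pairs in
    ``params.paralinguistic_effects``.
    """
    for name, langs, _shift in params.paralinguistic_effects:
        if name not in PARALINGUISTIC_FEATURES:
            raise ValueError(
                f"unknown paralinguistic feature in effects: {name!r}")
    rng = np.random.default_rng(params.seed + 1)
    n_feat = len(PARALINGUISTIC_FEATURES)
    # language-specific baseline means, fixed by the seed
    base = {lang: rng.normal(0.0, 1.0, size=n_feat)
            for lang in params.languages}
    shifts = {(name, lang): shift
              for name, langs, shift in params.paralinguistic_effects
              for lang in langs}
    rows = []
    for rec in subjects:
        mu = base[rec.language].copy()
        if rec.group == "AD":
            for j, name in enumerate(PARALINGUISTIC_FEATURES):
                mu[j] += shifts.get((name, rec.language), 0.0)
        rows.append(mu + rng.normal(0.0, 1.0, size=n_feat))
    df = pd.DataFrame(rows, columns=list(PARALINGUISTIC_FEATURES),
                      index=[r.subject_id for r in subjects])
    if ground_truth is not None:
        for name, langs, shift in params.paralinguistic_effects:
            ground_truth.effects[name] = (frozenset(langs),
                                          int(np.sign(shift)),
                                          abs(float(shift)))
    return df


def cohort_to_chat(record: SubjectRecord) -> str:
    """Render a subject record as a minimal CHAT document."""
    lines = ["@Begin", f"@Languages:\t{record.language}",
             f"@ID:\t{record.language}|synth|{record.subject_id}|"
             f"{record.group}|"]
    for utt in record.transcript.utterances:
        words = " ".join(t.surface for t in utt)
        lines.append(f"*PAR:\t{words}")
    lines.append("@End")
    return "\n".join(lines) + "\n"
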