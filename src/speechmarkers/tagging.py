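"""Part-of-speech tagging and head assignment behind a backend contract.

The syntactic features only need Universal POS tags and signed token
distances to the syntactic head.  Any callable with the ``Tagger`` contract
(token lists in, ``TaggedToken`` lists out) can back them; the packaged
default is a deterministic lexicon tagger with a small rule-based head
assigner, which needs no model download and tags the controlled vocabulary
of the synthetic cohorts exactly.  A pretrained tagger (e.g. a spaCy
pipeline) can be adapted to the same contract for real transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

from .ingest import FILLER_WORDS, Transcript

UPOS_TAGS = (
    "ADJ", "ADP", "ADV", "AUX", "CCONJ", "DET", "INTJ", "NOUN", "NUM",
    "PART", "PRON", "PROPN", "PUNCT", "SCONJ", "SYM", "VERB", "X",
)

OPEN_CLASS = frozenset({"ADJ", "ADV", "INTJ", "NOUN", "PROPN", "VERB"})
CLOSED_CLASS = frozenset({"ADP", "AUX", "CCONJ", "SCONJ", "DET", "NUM",
                          "PART", "PRON"})


@dataclass(frozen=True)
class TaggedToken:
    surface: str
    upos: str
    head_offset: int  # signed distance to the head token; 0 for the root

    def __post_init__(self) -> None:
        if self.upos not in UPOS_TAGS:
            raise ValueError(f"unknown UPOS tag {self.upos!r}")


class Tagger(Protocol):
    def __call__(self, transcript: Transcript) -> list[list[TaggedToken]]:
        ...


_EN_TAGS: dict[str, str] = {
    "the": "DET", "a": "DET", "an": "DET", "this": "DET", "that": "DET",
    "his": "DET", "her": "DET", "some": "DET",
    "is": "AUX", "are": "AUX", "was": "AUX", "were": "AUX", "has": "AUX",
    "have": "AUX", "be": "AUX",
    "he": "PRON", "she": "PRON", "it": "PRON", "they": "PRON", "there": "PRON",
    "i": "PRON", "we": "PRON", "you": "PRON", "him": "PRON", "them": "PRON",
    "and": "CCONJ", "but": "CCONJ", "or": "CCONJ",
    "while": "SCONJ", "because": "SCONJ", "when": "SCONJ",
    "in": "ADP", "on": "ADP", "of": "ADP", "into": "ADP", "from": "ADP",
    "at": "ADP", "with": "ADP", "over": "ADP",
    "to": "PART", "not": "PART",
    "up": "ADV", "down": "ADV", "out": "ADV", "off": "ADV", "here": "ADV",
    "outside": "ADV",
    "little": "ADJ", "young": "ADJ", "small": "ADJ", "open": "ADJ",
    "full": "ADJ", "high": "ADJ", "wet": "ADJ", "dry": "ADJ", "clean": "ADJ",
    "messy": "ADJ", "sweet": "ADJ", "busy": "ADJ", "drawn": "ADJ",
    "one": "NUM", "two": "NUM", "three": "NUM",
    "stealing": "VERB", "watching": "VERB", "washing": "VERB",
    "drying": "VERB", "standing": "VERB", "falling": "VERB",
    "reaching": "VERB", "running": "VERB", "overflowing": "VERB",
    "wobbling": "VERB", "laughing": "VERB", "spilling": "VERB",
    "looking": "VERB", "taking": "VERB", "see": "VERB", "falls": "VERB",
    "steals": "VERB", "watches": "VERB",
}

_FR_TAGS: dict[str, str] = {
    "le": "DET", "la": "DET", "les": "DET", "un": "DET", "une": "DET",
    "des": "DET", "sa": "DET", "son": "DET", "ce": "DET", "cette": "DET",
    "est": "AUX", "sont": "AUX", "a": "AUX", "ont": "AUX",
    "il": "PRON", "elle": "PRON", "ils": "PRON", "elles": "PRON",
    "on": "PRON", "y": "PRON", "qui": "PRON", "se": "PRON", "je": "PRON",
    "et": "CCONJ", "mais": "CCONJ", "ou": "CCONJ",
    "que": "SCONJ", "quand": "SCONJ", "parce": "SCONJ",
    "dans": "ADP", "sur": "ADP", "de": "ADP", "du": "ADP", "au": "ADP",
    "à": "ADP", "avec": "ADP", "pour": "ADP", "en": "ADP",
    "ne": "PART", "pas": "PART",
    "là": "ADV", "ici": "ADV", "dehors": "ADV", "voilà": "ADV",
    "petit": "ADJ", "petite": "ADJ", "ouvert": "ADJ", "ouverte": "ADJ",
    "plein": "ADJ", "pleine": "ADJ", "propre": "ADJ", "mouillé": "ADJ",
    "sec": "ADJ", "haut": "ADJ", "occupée": "ADJ",
    "vole": "VERB", "regarde": "VERB", "tombe": "VERB", "déborde": "VERB",
    "lave": "VERB", "sèche": "VERB", "coule": "VERB", "vacille": "VERB",
    "monte": "VERB", "essuie": "VERB", "voit": "VERB", "prend": "VERB",
}

_TAG_TABLES = {"en": _EN_TAGS, "fr": _FR_TAGS}


class LexiconTagger:
    """Deterministic word-list tagger with rule-based head assignment.

    Unknown words default to NOUN (the transcripts are noun-heavy picture
    descriptions); fillers tag as INTJ.  Heads: the first VERB (else AUX,
    else the first word) of an utterance is the root; determiners and
    adjectives attach to the next noun, everything else to the root.
    """

    def __init__(self, language: str = "en") -> None:
        self.language = language
        self._table = _TAG_TABLES.get(language, _EN_TAGS)

    def _tag_word(self, w: str) -> str:
        lw = w.lower()
        if lw in FILLER_WORDS:
            return "INTJ"
        return self._table.get(lw, "NOUN")

    def __call__(self, transcript: Transcript) -> list[list[TaggedToken]]:
        out: list[list[TaggedToken]] = []
        for utt in transcript.utterances:
            tags = [("PUNCT" if not t.is_word else self._tag_word(t.surface))
                    for t in utt]
            root = next((i for i, tg in enumerate(tags) if tg == "VERB"),
                        None)
            if root is None:
                root = next((i for i, tg in enumerate(tags) if tg == "AUX"),
                            0)
            tagged: list[TaggedToken] = []
            for i, (tok, tg) in enumerate(zip(utt, tags)):
                if i == root:
                    head = i
                elif tg in ("DET", "ADJ"):
                    head = next((j for j in range(i + 1, len(tags))
                                 if tags[j] in ("NOUN", "PROPN")), root)
                else:
                    head = root
                tagged.append(TaggedToken(tok.surface, tg, head - i))
            out.append(tagged)
        return out


def get_tagger(language: str) -> LexiconTagger:
    return LexiconTagger(language)
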