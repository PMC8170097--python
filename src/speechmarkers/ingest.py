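"""Reading and normalizing inputs: CHAT transcripts, audio, IU lexicons.

The picture-description transcripts follow the TalkBank CHAT convention:
speaker tiers (``*PAR:`` for the participant, ``*INV:`` for the
investigator), dependent tiers (``%mor:`` etc., ignored here) and inline
annotation codes.  Only the participant tier is analyzed — the features
describe the patient, not the examiner.

The information-unit (IU) lexicon maps each of the 16 content elements of
the Cookie Theft picture (boy, girl, woman, ...) to a set of synonymous
keywords ("the boy" may be called "brother" or "son") together with the
element's location in the picture under three spatial division schemes
(halves, quadrants, vertical stripes).
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "Token",
    "Transcript",
    "Waveform",
    "SubjectRecord",
    "IUEntry",
    "IULexicon",
    "Mention",
    "MentionSequence",
    "ChatParseError",
    "EmptyTranscriptError",
    "LexiconError",
    "IU_NAMES",
    "FILLER_WORDS",
    "parse_chat",
    "word_count",
    "load_lexicon",
    "match_mentions",
    "read_wav",
]

IU_NAMES = (
    "boy", "girl", "woman", "kitchen", "exterior", "cookie", "jar", "stool",
    "sink", "plate", "dishcloth", "water", "window", "cupboard", "dish",
    "curtain",
)

HALVES = ("left", "right")
QUADRANTS = ("NE", "NW", "SE", "SW")
STRIPES = ("most-left", "center-left", "center-right", "most-right")

#: filled pauses kept as word tokens by default (config flag to exclude)
FILLER_WORDS = frozenset({"uh", "um", "er", "eh", "euh", "hum", "ben", "hein"})

_TERMINATORS = {".", "?", "!"}


class ChatParseError(ValueError):
    """A tier line could not be parsed; the message names the line."""


class EmptyTranscriptError(ValueError):
    """The requested speaker has no utterances in the document."""


class LexiconError(ValueError):
    """An IU lexicon config failed validation."""


@dataclass(frozen=True)
class Token:
    surface: str
    is_word: bool = True


@dataclass
class Transcript:
    """Ordered utterances of one speaker; each utterance is a token list."""

    utterances: list[list[Token]]

    def words(self) -> Iterator[str]:
        for utt in self.utterances:
            for tok in utt:
                if tok.is_word:
                    yield tok.surface

    def word_tokens(self) -> list[str]:
        return list(self.words())

    @property
    def n_utterances(self) -> int:
        return len(self.utterances)


@dataclass
class Waveform:
    """Mono audio at a given sampling rate."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("waveform must be mono (1-D samples)")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class SubjectRecord:
    """One participant: transcript, metadata and (optionally) audio."""

    subject_id: str
    language: str          # "en" | "fr"
    group: str             # "HC" | "AD"
    transcript: Transcript
    age: Optional[float] = None
    waveform: Optional[Waveform] = None
    duration_s: Optional[float] = None  # participant response duration

    def __post_init__(self) -> None:
        if self.language not in ("en", "fr"):
            raise ValueError(f"unknown language {self.language!r}")
        if self.group not in ("HC", "AD"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.duration_s is not None and self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


@dataclass(frozen=True)
class IUEntry:
    name: str
    keywords: frozenset[str]  # canonical lowercased forms
    half: str
    quadrant: str
    stripe: str


# minimal per-language inflection tables: surface variants generated from the
# canonical keyword so plural mentions count without a lemmatizer
def _en_variants(word: str) -> set[str]:
    out = {word, word + "s"}
    if re.search(r"(s|x|z|ch|sh)$", word):
        out.add(word + "es")
    if word.endswith("y") and not re.search(r"[aeiou]y$", word):
        out.add(word[:-1] + "ies")
    return out


def _fr_variants(word: str) -> set[str]:
    out = {word, word + "s"}
    if re.search(r"(eau|eu|ou)$", word):
        out.add(word + "x")
    return out


_VARIANT_FNS = {"en": _en_variants, "fr": _fr_variants}


@dataclass
class IULexicon:
    """The 16 Cookie-Theft information units with keywords and regions."""

    language: str
    ius: list[IUEntry]
    # match table: variant word tuple -> (canonical keyword, iu name),
    # sorted longest-first for greedy matching
    _patterns: list[tuple[tuple[str, ...], str, str]] = field(
        default_factory=list, repr=False)

    def __post_init__(self) -> None:
        errors = []
        names = [e.name for e in self.ius]
        missing = set(IU_NAMES) - set(names)
        extra = set(names) - set(IU_NAMES)
        if missing:
            errors.append(f"missing IUs: {sorted(missing)}")
        if extra:
            errors.append(f"unknown IUs: {sorted(extra)}")
        for e in self.ius:
            if not e.keywords:
                errors.append(f"IU {e.name!r}: empty keyword set")
            if e.half not in HALVES:
                errors.append(f"IU {e.name!r}: unknown half {e.half!r}")
            if e.quadrant not in QUADRANTS:
                errors.append(f"IU {e.name!r}: unknown quadrant {e.quadrant!r}")
            if e.stripe not in STRIPES:
                errors.append(f"IU {e.name!r}: unknown stripe {e.stripe!r}")
        if errors:
            raise LexiconError("; ".join(errors))
        self._build_patterns()

    def _build_patterns(self) -> None:
        variants = _VARIANT_FNS.get(self.language, _en_variants)
        pats: dict[tuple[str, ...], tuple[str, str]] = {}
        for entry in self.ius:
            for kw in sorted(entry.keywords):
                words = kw.split()
                # inflect only the last word of a multi-word keyword
                for last in variants(words[-1]):
                    key = tuple(words[:-1] + [last])
                    # first writer wins; canonical keywords never collide
                    # across IUs in the shipped configs
                    pats.setdefault(key, (kw, entry.name))
        self._patterns = sorted(
            ((k, v[0], v[1]) for k, v in pats.items()),
            key=lambda t: (-len(t[0]), t[0]))

    @property
    def entries(self) -> dict[str, IUEntry]:
        return {e.name: e for e in self.ius}

    def region_of(self, iu_name: str, division: str) -> str:
        e = self.entries[iu_name]
        return {"halves": e.half, "quadrants": e.quadrant,
                "stripes": e.stripe}[division]

    def regions(self, division: str) -> Sequence[str]:
        return {"halves": HALVES, "quadrants": QUADRANTS,
                "stripes": STRIPES}[division]


@dataclass(frozen=True)
class Mention:
    position: int      # index into the flattened word-token stream
    keyword: str       # canonical keyword form
    iu_name: str


MentionSequence = list  # list[Mention]; positions strictly increasing


# ---------------------------------------------------------------------------
# CHAT parsing

_BULLET_RE = re.compile("\x15[^\x15]*\x15|•[^•]*•")
_BRACKET_RE = re.compile(r"\[[^\]]*\]")
_PAREN_RE = re.compile(r"\(([^)]*)\)")
_TIER_RE = re.compile(r"^\*([A-Za-z0-9]+):\s*(.*)$")

_UNINTELLIGIBLE = {"xxx", "yyy", "www"}


def _clean_utterance(text: str) -> list[Token]:
    text = _BULLET_RE.sub(" ", text)
    # drop paralinguistic events (&=laughs) and phonological fragments (&+fr)
    text = re.sub(r"&[=+]\S+", " ", text)
    # filled pauses &-uh -> keep the word itself
    text = re.sub(r"&-(\S+)", r"\1", text)
    # bracketed codes: retracing [/], [//], comments [=! ...], [% ...] ...
    # the retraced words themselves are kept
    text = _BRACKET_RE.sub(" ", text)
    # expand shortenings: (be)cause -> because
    text = _PAREN_RE.sub(r"\1", text)
    # angle brackets only group words for a following code
    text = text.replace("<", " ").replace(">", " ")
    # special utterance terminators (+..., +/.) -> plain terminator
    text = re.sub(r"\+[./!?]+", ".", text)
    text = text.replace("„", " ").replace("‡", " ").replace(",", " ")
    tokens: list[Token] = []
    for raw in text.split():
        # strip inline markers and citation suffixes (word@o)
        w = raw.split("@")[0]
        w = w.strip(":;^")
        if not w:
            continue
        if w in _TERMINATORS:
            tokens.append(Token(w, is_word=False))
            continue
        core = w.rstrip("".join(_TERMINATORS))
        trailing = w[len(core):]
        if core:
            if core.lower() not in _UNINTELLIGIBLE:
                tokens.append(Token(core, is_word=True))
        for ch in trailing:
            tokens.append(Token(ch, is_word=False))
    return tokens


def _split_sentences(tokens: list[Token]) -> list[list[Token]]:
    """Split a cleaned tier line at utterance terminators."""
    out: list[list[Token]] = []
    cur: list[Token] = []
    for tok in tokens:
        cur.append(tok)
        if not tok.is_word and tok.surface in _TERMINATORS:
            out.append(cur)
            cur = []
    if cur:
        out.append(cur)
    return out


def parse_chat(raw_text: str, speaker: str = "PAR") -> Transcript:
    """Parse a CHAT document and return the given speaker's utterances.

    Markup (timing bullets, event codes, retracing/repetition markers) is
    stripped; retraced words are kept; shortenings like ``(be)cause`` are
    expanded.  Word tokens and sentence-final punctuation are retained with
    ``is_word`` flags.

    Raises
    ------
    EmptyTranscriptError
        if the document has no utterances for *speaker*.
    ChatParseError
        on a malformed tier line.
    """
    utterances: list[list[Token]] = []
    current: Optional[str] = None  # accumulating utterance for our speaker
    for lineno, line in enumerate(raw_text.splitlines(), start=1):
        if not line.strip():
            continue
        first = line[0]
        if first in ("@", "%"):
            if current is not None:
                utterances.extend(_split_sentences(_clean_utterance(current)))
                current = None
            continue
        if first == "\t" or first == " ":
            if current is not None:
                current += " " + line.strip()
            continue
        if first == "*":
            if current is not None:
                utterances.extend(_split_sentences(_clean_utterance(current)))
                current = None
            m = _TIER_RE.match(line)
            if m is None:
                raise ChatParseError(
                    f"malformed tier line {lineno}: {line.strip()!r}")
            if m.group(1).upper() == speaker.upper():
                current = m.group(2)
            continue
        raise ChatParseError(f"unrecognized line {lineno}: {line.strip()!r}")
    if current is not None:
        utterances.extend(_split_sentences(_clean_utterance(current)))
    utterances = [u for u in utterances if u]
    if not utterances:
        raise EmptyTranscriptError(f"no utterances for speaker *{speaker}")
    return Transcript(utterances)


def word_count(transcript: Transcript, exclude_fillers: bool = False) -> int:
    """Number of word tokens (punctuation excluded).

    Filled pauses ("uh", "euh", ...) count as words by default; set
    ``exclude_fillers`` to drop them.
    """
    n = 0
    for w in transcript.words():
        if exclude_fillers and w.lower() in FILLER_WORDS:
            continue
        n += 1
    return n


# ---------------------------------------------------------------------------
# Lexicon loading and mention matching

def _default_lexicon_path(language: str) -> Path:
    res = resources.files("speechmarkers.data") / f"lexicon_{language}.json"
    with resources.as_file(res) as p:
        return Path(p)


def load_lexicon(path: Optional[str | Path] = None,
                 language: str = "en") -> IULexicon:
    """Load and validate an IU lexicon config (packaged default if no path).

    The config is JSON with keys ``language`` and ``ius``, each IU entry
    carrying ``name``, ``keywords`` and region labels ``half``/``quadrant``/
    ``stripe``.  Keywords are lowercased and deduplicated.
    """
    if path is None:
        path = _default_lexicon_path(language)
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    lang = data.get("language", language)
    entries = []
    for iu in data.get("ius", []):
        kws = frozenset(k.strip().lower() for k in iu.get("keywords", [])
                        if k.strip())
        entries.append(IUEntry(
            name=iu.get("name", ""), keywords=kws,
            half=iu.get("half", ""), quadrant=iu.get("quadrant", ""),
            stripe=iu.get("stripe", "")))
    return IULexicon(language=lang, ius=entries)


def _norm_word(w: str) -> str:
    w = w.lower()
    w = w.strip("'’-")
    # l'eau / d'eau -> eau
    m = re.match(r"^[ldcjmnst]['’](.+)$", w)
    if m:
        w = m.group(1)
    return unicodedata.normalize("NFC", w)


def match_mentions(transcript: Transcript, lexicon: IULexicon) -> list[Mention]:
    """Match IU keywords over the word-token stream.

    Matching is case-insensitive, longest-match-first (a multi-word keyword
    like "cookie jar" beats its single-word prefix), non-overlapping; each
    matched span yields exactly one mention, ordered by position.
    """
    words = [_norm_word(w) for w in transcript.words()]
    mentions: list[Mention] = []
    i = 0
    n = len(words)
    while i < n:
        matched = False
        for pat, keyword, iu_name in lexicon._patterns:
            k = len(pat)
            if i + k <= n and tuple(words[i:i + k]) == pat:
                mentions.append(Mention(i, keyword, iu_name))
                i += k
                matched = True
                break
        if not matched:
            i += 1
    return mentions


# ---------------------------------------------------------------------------
# Audio

def read_wav(path: str | Path, target_rate: int = 16000) -> Waveform:
    """Read a PCM WAV file, mixing to mono and resampling to *target_rate*."""
    from scipy.io import wavfile
    from scipy.signal import resample_poly

    rate, data = wavfile.read(path)
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    # normalize integer PCM to [-1, 1]
    peak = np.max(np.abs(data))
    if peak > 1.5:  # integer-scaled input
        data = data / 32768.0 if peak <= 32768 else data / peak
    if rate != target_rate:
        from math import gcd
        g = gcd(int(rate), int(target_rate))
        data = resample_poly(data, target_rate // g, rate // g)
        rate = target_rate
    return Waveform(samples=data, rate=int(rate))
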