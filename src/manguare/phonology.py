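"""Bora segmental and tonal phonology.

Bora has six vowels /i, ɨ, u, e, a, o/, each carrying one of two phonological
tones (H, written with an acute accent, or L, written with a grave accent),
and a consonant inventory in which nearly every plain consonant has a
palatalized counterpart (written here with an explicit ``^j^`` marker, e.g.
``k^j^``; the labialized velar is ``g^w^``).  Syllable structure is strictly
(C)V(h/ʔ): an optional single-consonant onset, an obligatory short or long
vowel nucleus, and an optional coda that can only be the glottal fricative
``h`` or the glottal stop ``ʔ``.  Long vowels (written as doubled vowel
symbols) can never be followed by a tautosyllabic glottal coda.

Two families of rhythmic units are defined over this material:

* **syllables** — types V, CV, VC, CVC, VV, CVV, with a weight of one mora
  (light, (C)V) or two moras (heavy, (C)VC and (C)VV);
* **vowel-to-vowel (V-to-V) intervals** — stretches from one vowel onset to
  the next, containing the nucleus plus *all* following consonants up to the
  next vowel (types V, VC, VCC, VV, VVC).  V-to-V intervals cross word
  boundaries within a phrase; consonants before the first vowel of a phrase
  form an untyped *anacrusis*.

Tone sequences are constrained by two phonotactic rules: (i) a sequence of
two low tones is prohibited except at the end of a tone phrase, and (ii) the
final tone of a word is high in phrase-medial position and low in
phrase-final position.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from functools import cached_property
from itertools import product
from typing import Iterable, Literal, Sequence

__all__ = [
    "Phoneme",
    "Syllable",
    "VtoVInterval",
    "TonePattern",
    "Word",
    "Phrase",
    "ParseError",
    "PhonotacticError",
    "ToneError",
    "PLAIN_CONSONANTS",
    "VOWELS",
    "tokenize",
    "detokenize",
    "syllabify",
    "classify_syllable",
    "segment_v_to_v",
    "classify_vtov",
    "tone_pattern",
    "validate_tones",
    "enumerate_licit_tone_patterns",
]

Position = Literal["medial", "final"]

#: Plain (non-palatalized) consonant inventory.
PLAIN_CONSONANTS = (
    "p", "b", "t", "d", "ʦ", "ʣ", "ʧ", "ʤ",
    "k", "g", "g^w^", "ʔ", "β", "r", "m", "n", "h",
)
#: Vowel letters (phonetically /u/ = [ɯ], /e/ = [ε]).
VOWELS = ("i", "ɨ", "u", "e", "a", "o")

#: Consonants that may precede another consonant / close a syllable.
GLOTTAL_SYMBOLS = frozenset({"h", "ʔ", "ʔ^j^"})

_PALATAL = "^j^"
_ACUTE = "́"  # combining acute  = H tone
_GRAVE = "̀"  # combining grave  = L tone

# Longest-match consonant token table (palatalized forms first).
_CONSONANT_TOKENS = tuple(
    sorted(
        [c + _PALATAL for c in PLAIN_CONSONANTS if c != "g^w^"]
        + list(PLAIN_CONSONANTS),
        key=len,
        reverse=True,
    )
)

# Characters silently skipped inside transcriptions: morpheme separator and
# segmentation dots as printed in glossed examples.
_IGNORED = {"-", "."}


class ParseError(ValueError):
    """Unparseable transcription; ``offset`` is the failing character index."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


class PhonotacticError(ValueError):
    """Input violates Bora phonotactics (e.g. a non-glottal CC cluster)."""


class ToneError(ValueError):
    """Tone marks are missing or inconsistent."""


@dataclass(frozen=True)
class Phoneme:
    """One segment: a consonant, or a (short or long) toned vowel."""

    symbol: str
    category: Literal["consonant", "vowel"]
    palatalized: bool = False
    long: bool = False
    glottal: bool = False
    tone: Literal["H", "L"] | None = None

    def __post_init__(self):
        if self.glottal and (
            self.category != "consonant" or self.symbol not in GLOTTAL_SYMBOLS
        ):
            raise ValueError(f"glottal flag invalid for {self.symbol!r}")
        if self.long and self.category != "vowel":
            raise ValueError("only vowels can be long")
        if self.tone is not None and self.category != "vowel":
            raise ValueError("only vowels carry tone")

    @property
    def is_vowel(self) -> bool:
        return self.category == "vowel"

    def __str__(self) -> str:  # canonical orthography
        if self.category == "consonant":
            return self.symbol
        mark = {"H": _ACUTE, "L": _GRAVE, None: ""}[self.tone]
        unit = unicodedata.normalize("NFC", self.symbol + mark)
        return unit * 2 if self.long else unit


def _consonant(symbol: str) -> Phoneme:
    return Phoneme(
        symbol=symbol,
        category="consonant",
        palatalized=symbol.endswith(_PALATAL),
        glottal=symbol in GLOTTAL_SYMBOLS,
    )


def _vowel(symbol: str, tone: str | None, long: bool = False) -> Phoneme:
    return Phoneme(symbol=symbol, category="vowel", long=long, tone=tone)


@dataclass(frozen=True)
class Syllable:
    """(C)V(h/ʔ) syllable: optional onset, nucleus, optional glottal coda."""

    onset: Phoneme | None
    nucleus: Phoneme
    coda: Phoneme | None = None

    def __post_init__(self):
        if self.coda is not None and not self.coda.glottal:
            raise PhonotacticError(
                f"syllable coda must be glottal, got {self.coda.symbol!r}"
            )
        if self.nucleus.long and self.coda is not None:
            raise PhonotacticError(
                "long vowels cannot be followed by h or ʔ within one syllable"
            )

    @property
    def type_label(self) -> str:
        label = "C" if self.onset else ""
        label += "VV" if self.nucleus.long else "V"
        if self.coda:
            label += "C"
        return label

    @property
    def weight_moras(self) -> int:
        """One mora for light (C)V, two for heavy (C)VV / (C)VC."""
        return 2 if (self.nucleus.long or self.coda) else 1

    @property
    def tone(self) -> str:
        return self.nucleus.tone

    @property
    def phonemes(self) -> tuple[Phoneme, ...]:
        return tuple(p for p in (self.onset, self.nucleus, self.coda) if p)

    def __str__(self) -> str:
        return "".join(str(p) for p in self.phonemes)


@dataclass(frozen=True)
class VtoVInterval:
    """Vowel-to-vowel interval: nucleus plus all consonants up to next vowel.

    ``source_span`` is ``(word_index, first_syllable_index)`` of the nucleus
    within its phrase; ``crosses_word_boundary`` is set when the trailing
    consonants belong to the next word.
    """

    nucleus: Phoneme
    consonants: tuple[Phoneme, ...] = ()
    source_span: tuple[int, int] | None = None
    crosses_word_boundary: bool = False

    @property
    def nucleus_len(self) -> int:
        return 2 if self.nucleus.long else 1

    @property
    def type_label(self) -> str:
        return classify_vtov(self)

    def __str__(self) -> str:
        return str(self.nucleus) + "".join(str(c) for c in self.consonants)


@dataclass(frozen=True)
class TonePattern:
    """Word-level tone sequence, one tone per syllable."""

    tones: tuple[str, ...]
    position: Position = "final"

    def __post_init__(self):
        if any(t not in ("H", "L") for t in self.tones):
            raise ToneError(f"tones must be H/L, got {self.tones}")

    def __str__(self) -> str:
        return "".join(self.tones)

    def __len__(self) -> int:
        return len(self.tones)


# ---------------------------------------------------------------------------
# Tokenization


def tokenize(text: str, require_tones: bool = True) -> list[Phoneme]:
    """Parse a canonical-orthography transcription into phonemes.

    Longest-match tokenization over the consonant table; vowels are a base
    letter plus an acute (H) or grave (L) accent.  Doubled identical vowel
    letters bearing *identical* tone marks merge into one long vowel; with
    differing tones they remain two short vowels in hiatus (e.g. ``nìì`` is
    one long L vowel while ``ìí`` is an L–H sequence).  Hyphens (morpheme
    breaks) and segmentation dots are skipped.
    """
    s = unicodedata.normalize("NFD", text)
    phonemes: list[Phoneme] = []
    i = 0
    while i < len(s):
        ch = s[i]
        if ch in _IGNORED or ch.isspace():
            i += 1
            continue
        matched = False
        for tok in _CONSONANT_TOKENS:
            if s.startswith(tok, i):
                # do not steal the base letter of a following palatal marker:
                # handled by longest-match ordering (palatalized first).
                phonemes.append(_consonant(tok))
                i += len(tok)
                matched = True
                break
        if matched:
            continue
        if ch in VOWELS:
            tone = None
            j = i + 1
            if j < len(s) and s[j] in (_ACUTE, _GRAVE):
                tone = "H" if s[j] == _ACUTE else "L"
                j += 1
            if tone is None and require_tones:
                raise ParseError(
                    f"vowel {ch!r} without tone mark at offset {i}", offset=i
                )
            prev = phonemes[-1] if phonemes else None
            if (
                prev is not None
                and prev.is_vowel
                and not prev.long
                and prev.symbol == ch
                and prev.tone == tone
            ):
                phonemes[-1] = _vowel(ch, tone, long=True)
            else:
                phonemes.append(_vowel(ch, tone))
            i = j
            continue
        raise ParseError(f"unknown symbol {ch!r} at offset {i}", offset=i)
    return phonemes


def detokenize(phonemes: Iterable[Phoneme]) -> str:
    """Inverse of :func:`tokenize` (round trip up to NFC normalization)."""
    return "".join(str(p) for p in phonemes)


# ---------------------------------------------------------------------------
# Syllabification


def syllabify(
    word: Sequence[Phoneme], allow_final_glottal_coda: bool = True
) -> list[Syllable]:
    """Parse a tokenized word into (C)V(h/ʔ) syllables.

    Any consonant immediately preceding a vowel is that vowel's onset; a
    glottal before a consonant (or word-finally, unless strict mode forbids
    it) closes the preceding syllable.  Raises :class:`PhonotacticError` for
    non-glottal consonant clusters, vowel-less residues, or a glottal coda
    after a long vowel.
    """
    word = list(word)
    syllables: list[Syllable] = []
    i = 0
    n = len(word)
    while i < n:
        onset = None
        if not word[i].is_vowel:
            nxt = word[i + 1] if i + 1 < n else None
            if nxt is None or not nxt.is_vowel:
                where = "word-finally" if nxt is None else f"before {nxt.symbol!r}"
                raise PhonotacticError(
                    f"consonant {word[i].symbol!r} cannot occur {where}: "
                    "only h and ʔ precede other consonants, as syllable codas"
                )
            onset = word[i]
            i += 1
        nucleus = word[i]
        i += 1
        coda = None
        if i < n and word[i].glottal:
            after = word[i + 1] if i + 1 < n else None
            if after is None or not after.is_vowel:
                # pre-consonantal or word-final glottal -> coda
                if after is None and not allow_final_glottal_coda:
                    raise PhonotacticError(
                        f"word-final glottal {word[i].symbol!r} rejected in "
                        "strict mode"
                    )
                if nucleus.long:
                    raise PhonotacticError(
                        "long vowels cannot be followed by h or ʔ within one "
                        "syllable"
                    )
                coda = word[i]
                i += 1
        elif i < n and not word[i].is_vowel:
            after = word[i + 1] if i + 1 < n else None
            if after is None or not after.is_vowel:
                raise PhonotacticError(
                    f"non-glottal consonant {word[i].symbol!r} cannot precede "
                    "another consonant or end a word"
                )
        syllables.append(Syllable(onset=onset, nucleus=nucleus, coda=coda))
    return syllables


def classify_syllable(s: Syllable) -> tuple[str, int]:
    """Return ``(type_label, weight_moras)`` for a syllable."""
    return s.type_label, s.weight_moras


SYLLABLE_TYPES = ("V", "CV", "VC", "CVC", "VV", "CVV")
VTOV_TYPES = ("V", "VC", "VCC", "VV", "VVC")


def classify_vtov(iv: VtoVInterval) -> str:
    """Label a V-to-V interval: V, VC, VCC (glottal+C only), VV or VVC."""
    ncons = len(iv.consonants)
    if iv.nucleus.long:
        if ncons > 1:
            raise PhonotacticError(
                "a long vowel can be followed by at most one consonant before "
                "the next vowel"
            )
        return "VV" if ncons == 0 else "VVC"
    if ncons > 2:
        raise PhonotacticError("more than two consonants between vowels")
    if ncons == 2 and not iv.consonants[0].glottal:
        raise PhonotacticError(
            "in a VCC interval the first consonant must be h or ʔ"
        )
    return ("V", "VC", "VCC")[ncons]


# ---------------------------------------------------------------------------
# Words and phrases


@dataclass(frozen=True)
class Word:
    """A tokenized word with cached syllabification."""

    transcription: str
    require_tones: bool = True

    @cached_property
    def phonemes(self) -> tuple[Phoneme, ...]:
        return tuple(tokenize(self.transcription, self.require_tones))

    @cached_property
    def syllables(self) -> tuple[Syllable, ...]:
        return tuple(syllabify(self.phonemes))

    @cached_property
    def tone_pattern_str(self) -> str:
        return "".join(s.tone for s in self.syllables)

    def __str__(self) -> str:
        return self.transcription


@dataclass(frozen=True)
class Phrase:
    """Ordered words with phrase positions (all medial but the last, unless
    given explicitly)."""

    words: tuple[Word, ...]
    positions: tuple[Position, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if not self.words:
            raise ValueError("a phrase needs at least one word")
        if self.positions is None:
            pos = ("medial",) * (len(self.words) - 1) + ("final",)
            object.__setattr__(self, "positions", pos)
        if len(self.positions) != len(self.words):
            raise ValueError("one position per word required")

    @classmethod
    def from_text(cls, text: str, require_tones: bool = True) -> "Phrase":
        words = tuple(
            Word(w, require_tones) for w in text.split() if w.strip()
        )
        return cls(words=words)

    @cached_property
    def syllables(self) -> tuple[Syllable, ...]:
        return tuple(s for w in self.words for s in w.syllables)

    @cached_property
    def word_index_of_syllable(self) -> tuple[int, ...]:
        out = []
        for wi, w in enumerate(self.words):
            out.extend([wi] * len(w.syllables))
        return tuple(out)

    def validate_tones(self) -> list[str]:
        """Phonotactic tone violations over all words (empty when valid)."""
        problems = []
        for w, pos in zip(self.words, self.positions):
            pat = tone_pattern(w.phonemes, position=pos)
            for v in validate_tones(pat, pos):
                problems.append(f"{w.transcription}: {v}")
        return problems

    def __str__(self) -> str:
        return " ".join(w.transcription for w in self.words)


def segment_v_to_v(
    phrase: Phrase | Word | str,
) -> tuple[list[Phoneme], list[VtoVInterval]]:
    """Segment a phrase into its anacrusis and V-to-V intervals.

    Returns ``(anacrusis, intervals)``: the untyped consonants preceding the
    first vowel of the phrase, and one interval per vowel nucleus.  Intervals
    run from each vowel onset up to (exclusive) the next vowel onset, crossing
    word boundaries; the interval count equals the syllable count.
    """
    if isinstance(phrase, str):
        phrase = Phrase.from_text(phrase)
    elif isinstance(phrase, Word):
        phrase = Phrase(words=(phrase,))
    flat: list[tuple[Phoneme, int]] = []  # (phoneme, word index)
    for wi, w in enumerate(phrase.words):
        flat.extend((p, wi) for p in w.phonemes)

    anacrusis: list[Phoneme] = []
    i = 0
    while i < len(flat) and not flat[i][0].is_vowel:
        anacrusis.append(flat[i][0])
        i += 1

    intervals: list[VtoVInterval] = []
    syll_counter = 0
    while i < len(flat):
        nucleus, word_idx = flat[i]
        i += 1
        consonants: list[Phoneme] = []
        crosses = False
        while i < len(flat) and not flat[i][0].is_vowel:
            c, wi = flat[i]
            consonants.append(c)
            crosses = crosses or (wi != word_idx)
            i += 1
        intervals.append(
            VtoVInterval(
                nucleus=nucleus,
                consonants=tuple(consonants),
                source_span=(word_idx, syll_counter),
                crosses_word_boundary=crosses,
            )
        )
        syll_counter += 1
    return anacrusis, intervals


# ---------------------------------------------------------------------------
# Tone patterns


def tone_pattern(
    word: Sequence[Phoneme] | Word | str, position: Position = "final"
) -> TonePattern:
    """One tone per syllable (a long vowel contributes a single tone)."""
    if isinstance(word, str):
        word = Word(word)
    if isinstance(word, Word):
        sylls = word.syllables
    else:
        sylls = syllabify(word)
    tones = []
    for s in sylls:
        if s.nucleus.tone is None:
            raise ToneError(f"syllable {s} lacks a tone mark")
        tones.append(s.nucleus.tone)
    return TonePattern(tones=tuple(tones), position=position)


def validate_tones(
    pattern: TonePattern | str, position: Position | None = None
) -> list[str]:
    """Check the two Bora tone phonotactic rules; return violations.

    Rule (i): a low–low sequence is licit only as the *final* two tones of a
    phrase-final word (the end of the tone phrase).  Rule (ii): the word-final
    tone is H phrase-medially and L phrase-finally.
    """
    if isinstance(pattern, str):
        pattern = TonePattern(tuple(pattern), position or "final")
    pos = position if position is not None else pattern.position
    t = pattern.tones
    n = len(t)
    if n == 0:
        raise ValueError("empty tone pattern")
    violations = []
    for i in range(n - 1):
        if t[i] == "L" and t[i + 1] == "L":
            if not (pos == "final" and i + 2 == n):
                violations.append(
                    f"rule (i): LL sequence at syllables {i + 1}-{i + 2} not "
                    "at the end of a tone phrase"
                )
    required = "H" if pos == "medial" else "L"
    if t[-1] != required:
        violations.append(
            f"rule (ii): word-final tone must be {required} in "
            f"phrase-{pos} position"
        )
    return violations


def enumerate_licit_tone_patterns(
    n: int, position: Position
) -> set[str]:
    """All tone patterns of length ``n`` satisfying the phonotactic rules.

    For trisyllabic words this yields exactly three of the eight logically
    possible patterns per position (HHH, HLH, LHH medially; HLL, HHL, LHL
    finally).
    """
    if n < 1:
        raise ValueError("syllable count must be >= 1")
    return {
        "".join(seq)
        for seq in product("HL", repeat=n)
        if not validate_tones(TonePattern(tuple(seq), position), position)
    }
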