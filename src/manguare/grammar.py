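"""Conventional structure and distinctiveness of manguaré messages.

In the drummed "talking mode", a message follows a rigid template (calling
messages: message type, addressee's clan, the marker *tùùtáβà-àbè/-ʤè*, a
proper name, the message content, and an end marker).  Because the drum
carries only two pitches and the interbeat rhythm, distinct spoken words can
collapse into the same drummed form.  A word's **drum signature** is the pair
(tone pattern, sequence of V-to-V interval types, with word-initial
consonants noted as an untyped "(C)" anacrusis); words sharing a signature
are *drum homophones*.

Drummed Bora counters this ambiguity with *enphrasing*: nouns and verbs take
special disyllabic markers (-úβù/-úβú for nouns, -ʔíhk^j^à/-ʔíhk^j^á for
verbs), and frequent words have conventional long replacement forms.  The
markers themselves are tonally identical and are distinguished purely by
rhythm, which this module quantifies.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .phonology import (
    Phrase,
    Position,
    Word,
    segment_v_to_v,
    tone_pattern,
)

__all__ = [
    "DrumSignature",
    "MessageTemplate",
    "CALLING_MESSAGE_TEMPLATE",
    "EnphrasingRules",
    "DEFAULT_ENPHRASING_RULES",
    "HomophoneReport",
    "MarkerContrastReport",
    "drum_signature",
    "homophone_classes",
    "apply_enphrasing",
    "marker_contrast_report",
]


@dataclass(frozen=True)
class DrumSignature:
    """All a listener hears: tone pattern plus rhythmic interval types."""

    tone_pattern: str
    rhythm: tuple[str, ...]
    anacrusis: bool = False

    def __post_init__(self):
        if len(self.tone_pattern) != len(self.rhythm):
            raise ValueError("one tone per rhythmic unit required")

    @property
    def rhythm_str(self) -> str:
        parts = (["(C)"] if self.anacrusis else []) + list(self.rhythm)
        return ".".join(parts)

    def __str__(self) -> str:
        return f"({self.tone_pattern}, {self.rhythm_str})"


def drum_signature(
    word: Word | Phrase | str, position: Position = "final"
) -> DrumSignature:
    """Tone pattern and V-to-V rhythm of a word or phrase as drummed.

    Word-initial consonants of an isolated word (or phrase-initial ones of a
    phrase) are reported as the presence of an untyped "(C)" anacrusis.
    """
    if isinstance(word, str):
        if not word.strip():
            raise ValueError("empty input has no drum signature")
        word = Phrase.from_text(word)
    elif isinstance(word, Word):
        word = Phrase(words=(word,))
    anacrusis, intervals = segment_v_to_v(word)
    tones = "".join(
        str(tone_pattern(w.phonemes, position=pos))
        for w, pos in zip(word.words, word.positions)
    )
    return DrumSignature(
        tone_pattern=tones,
        rhythm=tuple(iv.type_label for iv in intervals),
        anacrusis=bool(anacrusis),
    )


# ---------------------------------------------------------------------------
# Homophony / distinctiveness


def _mean(xs: Sequence[float]) -> float:
    return sum(xs) / len(xs) if xs else float("nan")


@dataclass(frozen=True)
class HomophoneReport:
    """Partitions of a lexicon by full signature, tone only, rhythm only.

    ``mean_class_size`` is the unweighted mean number of words per class;
    ``mean_candidates`` weights classes by their size and answers "how many
    candidate words does a heard signature suggest, on average over heard
    words" — the two coincide only for balanced partitions.
    """

    by_signature: dict[str, tuple[str, ...]]
    by_tone: dict[str, tuple[str, ...]]
    by_rhythm: dict[str, tuple[str, ...]]
    n_words: int

    @staticmethod
    def _sizes(partition: Mapping[str, tuple[str, ...]]) -> list[int]:
        return [len(v) for v in partition.values()]

    def n_classes(self, level: str = "signature") -> int:
        return len(getattr(self, f"by_{level}"))

    def mean_class_size(self, level: str = "signature") -> float:
        return _mean(self._sizes(getattr(self, f"by_{level}")))

    def mean_candidates(self, level: str = "signature") -> float:
        sizes = self._sizes(getattr(self, f"by_{level}"))
        return sum(s * s for s in sizes) / self.n_words

    def summary(self) -> dict:
        out = {"n_words": self.n_words}
        for level in ("signature", "tone", "rhythm"):
            out[f"n_{level}_classes"] = self.n_classes(level)
            out[f"mean_class_size_{level}"] = self.mean_class_size(level)
            out[f"mean_candidates_{level}"] = self.mean_candidates(level)
        return out


def homophone_classes(
    lexicon: Iterable[Word | str], position: Position = "final"
) -> HomophoneReport:
    """Partition a lexicon into drum-homophone classes.

    Words are grouped by full drum signature, and also by the two coarser
    keys — tone pattern only and rhythm pattern only — to compare the
    distinctiveness of tone against rhythm.
    """
    by_sig: dict[str, list[str]] = defaultdict(list)
    by_tone: dict[str, list[str]] = defaultdict(list)
    by_rhythm: dict[str, list[str]] = defaultdict(list)
    n = 0
    for w in lexicon:
        w = Word(w) if isinstance(w, str) else w
        sig = drum_signature(w, position)
        by_sig[str(sig)].append(w.transcription)
        by_tone[sig.tone_pattern].append(w.transcription)
        by_rhythm[sig.rhythm_str].append(w.transcription)
        n += 1
    freeze = lambda d: {k: tuple(v) for k, v in sorted(d.items())}
    return HomophoneReport(
        by_signature=freeze(by_sig),
        by_tone=freeze(by_tone),
        by_rhythm=freeze(by_rhythm),
        n_words=n,
    )


# ---------------------------------------------------------------------------
# Message template and enphrasing


@dataclass(frozen=True)
class MessageTemplate:
    """Ordered slots of a message type; formulaic slots carry no new info."""

    slots: tuple[tuple[str, bool], ...]  # (slot name, formulaic flag)

    def build(self, parts: Mapping[str, str | None]) -> list[str]:
        """Assemble slot contents in template order, skipping empty slots."""
        out = []
        for name, _ in self.slots:
            value = parts.get(name)
            if value:
                out.append(value)
        return out

    @property
    def slot_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.slots)


#: Calling-message template: marker precedes the proper-name slot.
CALLING_MESSAGE_TEMPLATE = MessageTemplate(
    slots=(
        ("type", True),
        ("clan", False),
        ("marker", True),
        ("name", False),
        ("content", False),
        ("end", True),
    )
)


@dataclass(frozen=True)
class EnphrasingRules:
    """Marker morphs per part of speech and position, plus long forms.

    ``markers[part_of_speech][position]`` is the disyllabic marker suffix;
    ``long_forms`` maps frequent lexemes to their conventional elaborated
    replacements (substituted *before* marking).
    """

    markers: Mapping[str, Mapping[str, str]]
    long_forms: Mapping[str, str] = field(default_factory=dict)


DEFAULT_ENPHRASING_RULES = EnphrasingRules(
    markers={
        "noun": {"medial": "úβú", "final": "úβù"},
        "verb": {"medial": "ʔíhk^j^á", "final": "ʔíhk^j^à"},
    },
    long_forms={
        # 'deer' -> 'deceased annatto deer, damaged animal'
        "nììβúg^w^à": "ìámé-tùùtáβààbè néébá-nììβúg^w^à",
    },
)


def apply_enphrasing(
    word: Word | str,
    part_of_speech: str,
    phrase_position: Position = "final",
    rules: EnphrasingRules = DEFAULT_ENPHRASING_RULES,
) -> str:
    """Elaborate a word the way drummed messages do.

    Lexeme-level long forms are substituted first, then the part-of-speech
    marker (whose final vowel tone obeys the phrase-position tone rule) is
    suffixed.  The result always re-tokenizes and re-syllabifies cleanly.
    """
    text = word.transcription if isinstance(word, Word) else word
    text = rules.long_forms.get(text, text)
    try:
        marker = rules.markers[part_of_speech][phrase_position]
    except KeyError:
        raise ValueError(
            f"no enphrasing marker for part of speech {part_of_speech!r}"
        ) from None
    elaborated = f"{text}-{marker}"
    # closure check: must remain phonotactically valid
    for chunk in elaborated.split():
        Word(chunk).syllables
    return elaborated


# ---------------------------------------------------------------------------
# Marker rhythm contrasts


@dataclass(frozen=True)
class MarkerContrastReport:
    """Rhythmic interval types that tell two markers apart.

    ``distinguishing_pairs`` lists (type under marker a, type under marker b)
    for each interval slot — starting from the interval containing the stem's
    final vowel — where the two suffixed forms differ; ``tones_identical``
    flags that tone alone cannot separate them.  ``duration_tests`` holds a
    two-sided rank-sum test per distinguishing pair when durations are given.
    """

    marker_a: str
    marker_b: str
    types_a: tuple[str, ...]
    types_b: tuple[str, ...]
    distinguishing_pairs: tuple[tuple[str, str], ...]
    tones_identical: bool
    duration_tests: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )


def marker_contrast_report(
    marker_a: str,
    marker_b: str,
    ibd_data=None,
    stem: str = "ʦíβà",
    position: Position = "final",
) -> MarkerContrastReport:
    """Compare two enphrasing markers rhythmically (and optionally by data).

    Both markers are suffixed to the same stem; the suffixed forms are
    segmented into V-to-V intervals and compared slot by slot from the
    interval that contains the stem-final vowel (the interval whose type the
    marker's initial consonants determine).  When ``ibd_data`` (a DataFrame
    with columns ``vtov_label`` and ``duration_s``) is given, each
    distinguishing type pair gets a Wilcoxon–Mann–Whitney test.
    """
    from .stats import rank_sum_test

    def marker_intervals(marker: str) -> tuple[str, ...]:
        _, stem_ivs = segment_v_to_v(Word(stem))
        _, ivs = segment_v_to_v(Word(f"{stem}-{marker}"))
        return tuple(iv.type_label for iv in ivs[len(stem_ivs) - 1:])

    types_a = marker_intervals(marker_a)
    types_b = marker_intervals(marker_b)
    pairs = tuple(
        (a, b) for a, b in zip(types_a, types_b) if a != b
    )
    tones_a = str(tone_pattern(marker_a.lstrip("-"), position))
    tones_b = str(tone_pattern(marker_b.lstrip("-"), position))
    tests: dict[tuple[str, str], tuple[float, float]] = {}
    if ibd_data is not None:
        for a, b in pairs:
            da = ibd_data.loc[ibd_data["vtov_label"] == a, "duration_s"]
            db = ibd_data.loc[ibd_data["vtov_label"] == b, "duration_s"]
            if len(da) and len(db):
                stat, p = rank_sum_test(da, db)
                tests[(a, b)] = (stat, p)
    return MarkerContrastReport(
        marker_a=marker_a,
        marker_b=marker_b,
        types_a=types_a,
        types_b=types_b,
        distinguishing_pairs=pairs,
        tones_identical=tones_a == tones_b,
        duration_tests=tests,
    )
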