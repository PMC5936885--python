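"""Drumbeat extraction, alignment and interbeat durations.

A manguaré message is a train of percussive beats on two drums tuned near
140 Hz (high, H) and 95 Hz (low, L); each beat corresponds to one syllable
of the underlying Bora phrase.  The rhythmic information lives in the
**interbeat durations** (IBDs): the time between the maximum-energy instants
of consecutive beats.  Because beats sit at vowel onsets, the pause after
beat *k* contains exactly the phonological material of the V-to-V interval
starting at vowel *k* — so every IBD is labelled here with the rhythmic unit
*starting* at its first beat, under all four competing hypotheses at once
(V-to-V type, syllable type, mora count, vowel length).

Performance errors ("slips of the drum") — a beat count or beat tone that
does not match the intended phrase — are reported as data, not raised as
errors, and slipped messages are excluded from statistics by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, hilbert, periodogram

from .phonology import Phrase, Syllable, VtoVInterval, segment_v_to_v

__all__ = [
    "BeatEvent",
    "DrummedMessage",
    "SlipReport",
    "IBDObservation",
    "ToneClassification",
    "PITCH_HIGH_HZ",
    "PITCH_LOW_HZ",
    "detect_beats",
    "classify_beat_tone",
    "align_beats",
    "compute_ibds",
    "spoken_vtov_durations",
    "observations_to_frame",
]

#: Nominal drum pitches (Hz) of the high and low drum.
PITCH_HIGH_HZ = 140.0
PITCH_LOW_HZ = 95.0
#: H/L decision boundary: geometric mean, symmetric on a log-frequency axis.
PITCH_BOUNDARY_HZ = float(np.sqrt(PITCH_HIGH_HZ * PITCH_LOW_HZ))


@dataclass(frozen=True)
class ToneClassification:
    """Outcome of spectral H/L classification of one beat."""

    label: Literal["H", "L"] | None
    pitch_hz: float | None
    low_confidence: bool = False


@dataclass(frozen=True)
class BeatEvent:
    """One drumbeat: instant of maximum acoustic energy, pitch and tone."""

    time_s: float
    pitch_hz: float | None = None
    tone_label: Literal["H", "L"] | None = None
    peak_amplitude: float | None = None
    low_confidence: bool = False

    def __post_init__(self):
        if self.time_s < 0:
            raise ValueError("beat time must be non-negative")


@dataclass(frozen=True)
class SlipReport:
    """Mismatch between a beat train and its intended phrase."""

    n_beats: int
    n_syllables: int
    tone_mismatches: tuple[tuple[int, str, str], ...] = ()
    # (syllable index, beat tone, syllable tone)

    @property
    def count_mismatch(self) -> bool:
        return self.n_beats != self.n_syllables

    @property
    def is_slip(self) -> bool:
        return self.count_mismatch or bool(self.tone_mismatches)


@dataclass(frozen=True)
class DrummedMessage:
    """Beat train aligned 1:1 (beat *k* ↔ syllable *k*) with a phrase."""

    beats: tuple[BeatEvent, ...]
    phrase: Phrase
    drummer_id: str = "1"

    def __post_init__(self):
        if len(self.beats) != len(self.phrase.syllables):
            raise ValueError(
                "aligned message requires one beat per syllable; use "
                "align_beats to obtain a slip report instead"
            )
        times = [b.time_s for b in self.beats]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("beats must be strictly time-ordered")


@dataclass(frozen=True)
class IBDObservation:
    """One duration datum, labelled under every rhythmic-unit hypothesis."""

    duration_s: float
    vtov_label: str
    syllable_label: str
    mora_label: int
    vlen_label: Literal["short", "long"]
    drummer_id: str
    speech_type: Literal["drummed", "spoken"] = "drummed"
    intra_word: bool = True

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("durations must be positive")


# ---------------------------------------------------------------------------
# Signal processing


def detect_beats(
    audio: np.ndarray,
    sample_rate: int,
    energy_window_s: float = 0.005,
    min_separation_s: float = 0.040,
    rel_threshold: float = 0.2,
    min_peak_energy: float = 1e-8,
    rise_window_s: float = 0.010,
    rise_ratio: float = 3.0,
    classify_tones: bool = True,
    tone_window_s: float = 0.080,
) -> list[BeatEvent]:
    """Locate percussive events in a mono waveform.

    The short-time energy envelope (a forward-looking window of
    ``energy_window_s``) is peak-picked with a minimum separation of
    ``min_separation_s``; each beat instant is the start of the window of
    maximum energy.  Peaks below ``rel_threshold`` of the strongest peak (or
    below the absolute floor ``min_peak_energy``) are ignored, so silence
    yields an empty list; peaks not preceded by an energy rise of at least
    ``rise_ratio`` within ``rise_window_s`` are ripples on a decaying tail,
    not onsets, and are ignored too.
    """
    x = np.asarray(audio, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("mono audio required")
    if x.size == 0:
        return []
    w = max(1, int(round(energy_window_s * sample_rate)))
    cs = np.concatenate([[0.0], np.cumsum(x * x)])
    env = cs[w:] - cs[:-w]  # env[i] = energy of x[i : i+w]
    if env.size == 0 or env.max() <= min_peak_energy:
        return []
    height = max(rel_threshold * env.max(), min_peak_energy)
    distance = max(1, int(round(min_separation_s * sample_rate)))
    peaks, _ = find_peaks(env, height=height, distance=distance)
    rise = max(1, int(round(rise_window_s * sample_rate)))
    peaks = [
        i for i in peaks
        if env[i] > rise_ratio * (env[i - rise] if i >= rise else 0.0)
    ]
    events = []
    for i in peaks:
        # refine: the window-sum argmax ripples at the pitch period; the
        # analytic (Hilbert) envelope of the local segment does not
        a, b = max(0, i - 4 * w), min(x.size, i + 4 * w)
        analytic = np.abs(hilbert(x[a:b]))
        lo, hi = max(0, i - 2 * w - a), min(b - a, i + 2 * w - a)
        i = a + lo + int(np.argmax(analytic[lo:hi]))
        seg_end = min(x.size, i + w)
        peak_amp = float(np.max(np.abs(x[i:seg_end]))) if seg_end > i else 0.0
        tone: ToneClassification | None = None
        if classify_tones:
            stop = min(x.size, i + int(round(tone_window_s * sample_rate)))
            tone = classify_beat_tone(x[i:stop], sample_rate)
        events.append(
            BeatEvent(
                time_s=i / sample_rate,
                pitch_hz=tone.pitch_hz if tone else None,
                tone_label=tone.label if tone else None,
                peak_amplitude=peak_amp,
                low_confidence=tone.low_confidence if tone else False,
            )
        )
    return events


def classify_beat_tone(
    segment: np.ndarray,
    sample_rate: int,
    f_high: float = PITCH_HIGH_HZ,
    f_low: float = PITCH_LOW_HZ,
    band: tuple[float, float] = (40.0, 300.0),
) -> ToneClassification:
    """Classify one beat as high- or low-drum from its dominant pitch.

    The dominant spectral peak within ``band`` decides: H if it lies closer
    (on a log-frequency axis) to ``f_high``, L if closer to ``f_low``; the
    decision boundary is their geometric mean (~115 Hz).  A peak in the
    middle fifth of the log-frequency gap is flagged ``low_confidence``; a
    segment with no energy in the band is unclassifiable (label ``None``).
    The segment should cover at least three periods of the low drum.
    """
    x = np.asarray(segment, dtype=np.float64)
    if x.size < 8:
        return ToneClassification(None, None, True)
    nfft = max(1 << 15, int(2 ** np.ceil(np.log2(x.size))))
    freqs, power = periodogram(x, fs=sample_rate, nfft=nfft)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(sel) or power[sel].max() <= 1e-14:
        return ToneClassification(None, None, True)
    pitch = float(freqs[sel][np.argmax(power[sel])])
    boundary = np.sqrt(f_high * f_low)
    label = "H" if pitch >= boundary else "L"
    margin = abs(np.log(pitch) - np.log(boundary)) / (
        np.log(f_high) - np.log(boundary)
    )
    return ToneClassification(label, pitch, low_confidence=margin < 0.2)


# ---------------------------------------------------------------------------
# Alignment and durations


def align_beats(
    beats: Sequence[BeatEvent],
    phrase: Phrase | str,
    drummer_id: str = "1",
    check_tones: bool = True,
) -> DrummedMessage | SlipReport:
    """Align a beat train 1:1 with the syllables of its intended phrase.

    Returns a :class:`DrummedMessage` when the beat count matches the
    syllable count and (if ``check_tones``) every classified beat tone
    matches its syllable tone; otherwise a :class:`SlipReport`.  Slips are
    data, not errors.
    """
    if isinstance(phrase, str):
        phrase = Phrase.from_text(phrase)
    syllables = phrase.syllables
    if len(beats) != len(syllables):
        return SlipReport(n_beats=len(beats), n_syllables=len(syllables))
    mismatches = []
    if check_tones:
        for k, (b, s) in enumerate(zip(beats, syllables)):
            if b.tone_label is not None and b.tone_label != s.tone:
                mismatches.append((k, b.tone_label, s.tone))
    if mismatches:
        return SlipReport(
            n_beats=len(beats),
            n_syllables=len(syllables),
            tone_mismatches=tuple(mismatches),
        )
    return DrummedMessage(beats=tuple(beats), phrase=phrase,
                          drummer_id=drummer_id)


def _label_observation(
    duration: float,
    interval: VtoVInterval,
    syllable: Syllable,
    intra_word: bool,
    drummer_id: str,
    speech_type: str,
) -> IBDObservation:
    vtov = interval.type_label
    return IBDObservation(
        duration_s=float(duration),
        vtov_label=vtov,
        syllable_label=syllable.type_label,
        mora_label=syllable.weight_moras,
        vlen_label="long" if interval.nucleus.long else "short",
        drummer_id=drummer_id,
        speech_type=speech_type,  # type: ignore[arg-type]
        intra_word=intra_word,
    )


def compute_ibds(message: DrummedMessage) -> list[IBDObservation]:
    """Interbeat durations of an aligned message, fully labelled.

    ``IBD_k = t_{k+1} - t_k`` is labelled with the V-to-V interval starting
    at vowel *k* (and, under the syllable hypothesis, with syllable *k*,
    whose own onset fell inside the *previous* interval).  ``intra_word`` is
    true iff syllables *k* and *k+1* belong to the same word; the last beat
    emits no duration.
    """
    if isinstance(message, SlipReport):
        raise ValueError("cannot compute IBDs from a slipped message")
    _, intervals = segment_v_to_v(message.phrase)
    syllables = message.phrase.syllables
    word_of = message.phrase.word_index_of_syllable
    times = [b.time_s for b in message.beats]
    out = []
    for k in range(len(times) - 1):
        out.append(
            _label_observation(
                duration=times[k + 1] - times[k],
                interval=intervals[k],
                syllable=syllables[k],
                intra_word=word_of[k] == word_of[k + 1],
                drummer_id=message.drummer_id,
                speech_type="drummed",
            )
        )
    return out


def spoken_vtov_durations(
    onsets: Sequence[float],
    phrase: Phrase | str,
    speaker_id: str = "1",
) -> list[IBDObservation]:
    """Durations between successive vowel onsets in spoken Bora.

    ``onsets`` holds one time (s) per vowel nucleus — the measure point set
    at the vowel onset — and must match the phrase's syllable count.  The
    resulting observations are labelled exactly like drummed IBDs, with
    ``speech_type="spoken"``.
    """
    if isinstance(phrase, str):
        phrase = Phrase.from_text(phrase)
    _, intervals = segment_v_to_v(phrase)
    syllables = phrase.syllables
    word_of = phrase.word_index_of_syllable
    if len(onsets) != len(syllables):
        raise ValueError(
            f"{len(onsets)} vowel onsets for {len(syllables)} vowels"
        )
    out = []
    for k in range(len(onsets) - 1):
        out.append(
            _label_observation(
                duration=onsets[k + 1] - onsets[k],
                interval=intervals[k],
                syllable=syllables[k],
                intra_word=word_of[k] == word_of[k + 1],
                drummer_id=speaker_id,
                speech_type="spoken",
            )
        )
    return out


_FRAME_COLUMNS = [
    "duration_s",
    "vtov_label",
    "syllable_label",
    "mora_label",
    "vlen_label",
    "drummer_id",
    "speech_type",
    "intra_word",
]


def observations_to_frame(
    observations: Sequence[IBDObservation],
    intra_word_only: bool = True,
    exclude_vv: bool = True,
) -> pd.DataFrame:
    """Tabulate observations for statistics.

    By default only intra-word durations are kept (cross-word intervals mix
    phrase-level pausing into the durations) and the exceedingly rare VV
    V-to-V type is dropped.
    """
    df = pd.DataFrame(
        [[getattr(o, c) for c in _FRAME_COLUMNS] for o in observations],
        columns=_FRAME_COLUMNS,
    )
    if intra_word_only and len(df):
        df = df[df["intra_word"]]
    if exclude_vv and len(df):
        df = df[df["vtov_label"] != "VV"]
    return df.reset_index(drop=True)
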