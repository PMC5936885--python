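# Methods

This note documents the models, conventions and numerical choices behind
the package, and what its synthetic experiments can and cannot show.

## Phonological model

Bora is modelled with six vowels /i, ɨ, u, e, a, o/, two level tones (H
written with an acute accent, L with a grave), phonemic vowel length
(doubled vowel letters), and a consonant inventory of 17 plain consonants
with palatalized counterparts (written with an explicit `^j^` marker; the
labialized velar is `g^w^`). Syllables are strictly (C)V(h/ʔ): optional
single-consonant onset, obligatory nucleus, optional glottal coda; long
vowels never take a tautosyllabic glottal coda. Consequences used
throughout: the only consonant clusters are glottal + consonant, and at
most two consonants can separate two vowels.

**Tokenization** is longest-match over the canonical token table on
NFD-normalized text; morpheme hyphens and segmentation dots are skipped.
Doubled identical vowel letters merge into one long vowel *only when their
tone marks agree*; otherwise they remain two short vowels in hiatus. This
single convention reconciles monosyllabic long-vowel words with
trisyllabic parses of sequences like *ìí* (L then H). Detokenization
inverts tokenization up to Unicode normalization. Word-final glottals are
accepted as codas by default (a strict mode rejects them), since the
syllable template does not forbid them.

**Rhythmic units.** Four labelings of the same material compete:

| hypothesis | unit types | how an interbeat duration is labelled |
|---|---|---|
| V-to-V | V, VC, VCC, VV, VVC | interval starting at the first beat's vowel |
| syllable | V, CV, VC, CVC, VV, CVV | syllable carrying the first beat |
| mora | 1, 2 | weight of that syllable ((C)V light; (C)VC, (C)VV heavy) |
| vowel length | short, long | nucleus length of the interval |

A V-to-V interval runs from a vowel onset to the next vowel onset
(half-open), crossing word boundaries; consonants before a phrase's first
vowel form an untyped anacrusis excluded from statistics. The labelling
convention — the pause after beat *k* carries the unit *starting* at vowel
*k* — reflects the physical situation (beats sit at vowel onsets) and is
what produces the syllable analysis's characteristic artefact: an onset
consonant is drummed inside the *previous* syllable's pause.

The VV interval type (long vowel immediately followed by another vowel) is
classified but excluded from models by default: it is vanishingly rare and
carries no usable data.

**Tone phonotactics.** Two rules are enforced: (i) a low–low tone sequence
is licit only as the final two tones of a phrase-final word; (ii) the
word-final tone is H phrase-medially and L phrase-finally. Tone phrases
are resolved at word granularity — the material gives no evidence about
word-internal tone-phrase ends, so position is a per-word property. The
resulting licit sets (3 of 8 trisyllabic patterns per position) are
verified exhaustively against a brute-force filter.

## Beat processing

- **Detection.** The short-time energy envelope uses a forward-looking
  5 ms window (so the envelope peaks at an event's onset rather than half
  a window late), peak-picked with a 40 ms minimum separation and a
  relative threshold of 0.2 of the strongest peak. Peaks not preceded by a
  ≥3× energy rise within 10 ms are ripples on a decaying tail, not onsets,
  and are discarded — necessary because the low drum's slow decay stays
  above threshold past the separation distance. The beat instant is then
  refined to the maximum of the analytic (Hilbert) envelope of the local
  segment, which is free of the pitch-period ripple that limits raw
  energy windows to ~3 ms accuracy; the refined instant is sample-accurate
  on clean signals and within ±2 ms at 20 dB SNR.
- **Tone classification.** The dominant periodogram peak in 40–300 Hz
  decides H vs L against the geometric-mean boundary of 140 and 95 Hz
  (≈115 Hz, symmetric on a log-frequency axis); estimates in the middle
  fifth of the log-gap are flagged low-confidence, and a band without
  energy is unclassifiable.
- **Alignment.** Beat trains align 1:1 with syllables. Count or tone
  mismatches produce a slip report rather than an exception; slipped
  messages are excluded from statistics by default, mirroring the
  exclusion of slips of the drum in corpus work.
- **Units.** Seconds internally, milliseconds in reports.

## Statistical models

Interbeat duration is regressed on DRUMMER × TYPE (and optionally
SPEECHTYPE, entered first) by OLS, with sequential (type I) sums of
squares in the entry order DRUMMER → TYPE → interaction so tables match
the conventional layout. With only two drummers, DRUMMER is a fixed
effect; mixed models are out of scope by design. Backward selection tests
each maximal term by a nested F-test at α = 0.05, dropping the least
significant until all maximal terms are significant. Models are compared
by adjusted R² (guarding the zero-variance corner case, where R² is
defined as 0).

**Simultaneous contrasts.** All unordered pairs of type levels are tested
within each drummer (6 types × 2 drummers → 30 comparisons; 4 V-to-V
types → 12). Cell means come from the fitted design (averaging over any
factor not in the family, e.g. SPEECHTYPE). Family-wise error is
controlled single-step: the contrast estimates' joint normal
approximation is sampled (10⁵ Monte Carlo draws, fixed seed), each draw
scaled by a shared chi factor with the model's residual degrees of freedom
(all statistics divide by the same σ̂), and each |t| is referred to the
null distribution of the maximum. Holm's step-down procedure is available
as a deterministic fallback; adjusted p-values are never below raw ones.
Calibration under an equal-means null is ~5% family-wise (measured 5.4%
over 5,000 simulated datasets).

**Duration scale.** Types are ordered by estimated mean; adjacent
non-significant pairs merge into equivalence classes, transitively. A
non-transitive significance pattern (a significant pair inside a merged
class) is flagged on the result and never silently resolved.

**Consistency scoring.** Each binary weight hypothesis predicts two
classes of syllable types (mora: {V, CV} vs the rest; vowel length:
{V, CV, VC, CVC} vs {VV, CVV}). Every pairwise verdict is classified as
coherent, differ-but-shouldn't, should-differ-but-doesn't, or
wrong-direction (significant with the heavier class shorter).

**Modality comparison.** For words attested in both registers, durations
are averaged per interval type within the word and the *types* are ranked
per modality; a word corresponds when the rankings agree. Two intervals of
the same type have no expected relative order, so only between-type order
is compared. Words with mismatched interval counts are skipped with a
warning.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes; it
is not an acoustic or lexical model of Bora.

- **Lexicon.** Words are built syllable by syllable under the (C)V(h/ʔ)
  template with structure probabilities: initial onset 0.65, hiatus
  (onsetless non-initial syllable) 0.22, long nucleus 0.18, glottal coda
  0.25. Onsetless syllables never follow a coda, a long nucleus or
  another onsetless syllable, and take a vowel different from the
  preceding nucleus. These constraints guarantee closure (every generated
  word re-tokenizes and re-syllabifies identically), keep VV intervals out
  of intra-word data, and let hiatus follow CV but never V syllables —
  which is exactly what produces the CV < V artefact under syllable
  labelling. Tone patterns are drawn uniformly from the licit set for the
  word's length and phrase position.
- **Durations.** `IBD = rate_d · base(type) + offset_d + N(0, σ²)` with
  base durations 0.30/0.32/0.34/0.36 s for V/VC/VVC/VCC and σ = 15 ms.
  Only the ~20 ms class spacing is empirically anchored; the absolute
  level and the Gaussian noise family are package choices, declared here,
  not asserted as corpus values. Drummer profiles default to rates
  1.00/1.15 and offsets 0/20 ms — individual drumming styles, which also
  make the DRUMMER × TYPE interaction real. The spoken register shifts
  the level (shortest class at half the drummed one) while preserving the
  20 ms spacing, since the four classes are separated by roughly the same
  amount in both registers.
- **Study conditions.** The default experiment corpus is 260 messages of
  10–20 words drawn from ~230 word types (170 phrase-medial, 60
  phrase-final), yielding ≈7,000 intra-word interbeat durations across
  two drummers, with 5% of messages carrying an injected slip (a dropped
  beat or flipped tone). The lexicon size matters: with very small lexica
  the hiatus rate — and with it the CV − V effect — fluctuates strongly
  between runs.
- **Audio.** Each beat is an exponentially decaying cosine (140 Hz with
  30 ms decay for H — the smaller drum rings shorter — and 95 Hz with
  60 ms for L) at constant peak amplitude starting exactly at the beat
  time, at 44.1 kHz; noise is white Gaussian specified as peak SNR.

**What passing tests show — and don't.** The Monte Carlo experiments show
that the pipeline recovers the structure the generator put in (the
four-class scale, the interaction, the labelling artefact, the modality
correspondence) at realistic sample sizes, and that its simultaneous
inference is calibrated. They cannot show that real drummed Bora has this
structure: real IBDs include phrase-final lengthening, tempo drift,
non-Gaussian motor noise and lexical frequency effects that the generator
deliberately omits, and real drum audio adds reverberation and variable
strike quality that the clean synthesis does not model.

## Problem sizes

Test-suite and acceptance-script experiments use 30–100 corpora of ≈7,000
durations for recovery properties, 400 (tests) or 200 (script) null
datasets of 800 rows for calibration, 1,000 beats (~5 minutes of audio)
for the signal chain, and 20–40 runs for the artefact and modality
properties — sizes chosen so each property is measured with comfortable
statistical margin.

## Known limitations

- Tone phrases are word-granular; word-internal tone-phrase boundaries
  (rule (i)) are not representable.
- The beat detector is tuned for clean, isolated percussive events; it is
  not a field-recording beat tracker and has no reverberation handling.
- The EAF reader supports a single time-aligned tier with H/L annotation
  values — a data-exchange convenience, not an ELAN implementation.
- The bundled 18-name lexicon is a synthetic stand-in constructed to
  realise the attested class structure (7 rhythm classes, 2 tone classes);
  apart from its three attested members the names are invented.
- `mean_candidates` vs `mean_class_size`: a heard signature's expected
  candidate count weights classes by size; both are reported because
  "average names per class" is ambiguous between them.
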