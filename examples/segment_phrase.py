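"""Segment a Bora phrase into syllables and vowel-to-vowel intervals.

The phrase 'káʔgúnúkòúβú ò áʔʦàkúnè' ("I am finishing the cahuana") is
drummed with 11 beats — one per syllable.  The two competing segmentations
differ in where consonants go: syllables keep their onsets, while V-to-V
intervals assign every consonant to the *preceding* vowel's interval, with
the phrase-initial k left over as an untyped anacrusis.
"""

from manguare.phonology import Phrase, segment_v_to_v

phrase = Phrase.from_text("káʔgúnúkòúβú ò áʔʦàkúnè")

print(f"phrase: {phrase}")
print(f"syllables ({len(phrase.syllables)}):",
      " . ".join(str(s) for s in phrase.syllables))
print("syllable types:   ",
      " ".join(s.type_label for s in phrase.syllables))

anacrusis, intervals = segment_v_to_v(phrase)
print(f"anacrusis: {''.join(p.symbol for p in anacrusis)!r}")
print(f"V-to-V intervals ({len(intervals)}):",
      " | ".join(str(iv) for iv in intervals))
print("interval types:   ",
      " ".join(iv.type_label for iv in intervals))

# Both segmentations produce the same number of units (= beats), but they
# label the pauses between beats differently: e.g. the first pause holds
# the whole interval áʔg (VCC) although the first *syllable* is káʔ (CVC).
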