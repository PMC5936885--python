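"""Enumerate the tone patterns Bora phonotactics actually allows.

Two rules constrain H/L tone sequences: no low–low sequence except at the
end of a tone phrase, and word-final H phrase-medially vs word-final L
phrase-finally.  For trisyllabic words this cuts the 8 logically possible
patterns down to 3 per position — which is why tone alone identifies a
heard word so poorly, and rhythm has to carry the contrast.
"""

from manguare.phonology import enumerate_licit_tone_patterns, validate_tones

for n in (1, 2, 3, 4):
    for position in ("medial", "final"):
        licit = sorted(enumerate_licit_tone_patterns(n, position))
        print(f"n={n} {position:6s}: {len(licit)}/{2 ** n} licit -> "
              f"{', '.join(licit)}")

print("\nwhy LLH is out phrase-medially:",
      validate_tones("LLH", "medial"))
print("why HHH is out phrase-finally:",
      validate_tones("HHH", "final"))
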