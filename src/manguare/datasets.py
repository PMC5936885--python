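"""Small bundled lexica used by examples and the distinctiveness analysis.

``synthetic_name_lexicon`` is a *synthetic* stand-in for the set of 18
trisyllabic proper names attested in drummed calling messages: 18
phonotactically and tonally valid trisyllabic names constructed so that the
set realises 7 distinct rhythmic signatures and 2 distinct tone patterns
(LHL and HHL, nine names each), the class structure reported for the real
name set.  It embeds the three attested names that contrast in their first
V-to-V interval (ʤìíʔ^j^ò — V, nèèpáh^j^ù — VVC, òʔʣíβà — VCC); the
remaining 15 names are invented.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .phonology import Word

__all__ = ["synthetic_name_lexicon", "FIG3_PHRASE", "LONG_FORM_DEER"]

#: Worked-example phrase: 'I am finishing the cahuana (manioc starch drink)'.
FIG3_PHRASE = "káʔgúnúkòúβú ò áʔʦàkúnè"

#: Conventional long form replacing the deer name in drummed messages.
LONG_FORM_DEER = ("nììβúg^w^à", "ìámé-tùùtáβààbè néébá-nììβúg^w^à-úβù")


def synthetic_name_lexicon(as_words: bool = True):
    """Load the synthetic trisyllabic proper-name lexicon.

    Returns a list of :class:`~manguare.phonology.Word` (default) or the raw
    DataFrame with columns ``word_id, transcription, part_of_speech, slot``.
    """
    ref = resources.files("manguare.data") / "synthetic_name_lexicon.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    if not as_words:
        return df
    return [Word(t) for t in df["transcription"]]
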