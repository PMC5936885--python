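"""Segmental parsing, syllabification, V-to-V segmentation and tone rules."""

import unicodedata
from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from manguare.phonology import (
    ParseError,
    PhonotacticError,
    Phrase,
    TonePattern,
    Word,
    detokenize,
    enumerate_licit_tone_patterns,
    segment_v_to_v,
    syllabify,
    tokenize,
    tone_pattern,
    validate_tones,
)
from manguare.synth import generate_lexicon

FIG3 = "káʔgúnúkòúβú ò áʔʦàkúnè"


def nfc(s):
    return unicodedata.normalize("NFC", s)


class TestTokenize:
    @pytest.mark.parametrize(
        "text, symbols, tones",
        [
            ("ʦíβàʔíhk^j^à",
             ["ʦ", "i", "β", "a", "ʔ", "i", "h", "k^j^", "a"],
             ["H", "L", "H", "L"]),
            ("bá", ["b", "a"], ["H"]),
            ("g^w^á", ["g^w^", "a"], ["H"]),
        ],
    )
    def test_segments_and_tones(self, text, symbols, tones):
        ph = tokenize(text)
        assert [p.symbol for p in ph] == symbols
        assert [p.tone for p in ph if p.is_vowel] == tones

    def test_identical_tone_doubling_merges_to_long_vowel(self):
        ph = tokenize("nìì")
        assert len(ph) == 2 and ph[1].long and ph[1].tone == "L"

    def test_differing_tones_stay_in_hiatus(self):
        ph = tokenize("ìí")
        assert len(ph) == 2
        assert not ph[0].long and not ph[1].long
        assert (ph[0].tone, ph[1].tone) == ("L", "H")

    def test_unknown_symbol_reports_offset(self):
        with pytest.raises(ParseError) as exc:
            tokenize("báx")
        # offsets count NFD characters: b, a, combining acute, x
        assert exc.value.offset == 3

    def test_vowel_without_tone_raises_unless_disabled(self):
        with pytest.raises(ParseError):
            tokenize("ba")
        assert tokenize("ba", require_tones=False)[1].tone is None

    @pytest.mark.parametrize(
        "text",
        ["ʦíβàʔíhk^j^à", "nììβúg^w^à", "ʤìíʔ^j^ò", "káʔgúnúkòúβú",
         "mèg^w^ák^j^ùtéʔíhk^j^àkì"],
    )
    def test_round_trip(self, text):
        assert detokenize(tokenize(text)) == nfc(text)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 2**20))
    def test_round_trip_on_generated_words(self, seed):
        (word,) = generate_lexicon(1, seed=seed)
        assert detokenize(tokenize(word.transcription)) == nfc(
            word.transcription
        )


class TestSyllabify:
    def test_fig3_first_word_has_six_syllables(self):
        sylls = Word("káʔgúnúkòúβú").syllables
        assert [nfc(str(s)) for s in sylls] == [
            nfc(x) for x in ["káʔ", "gú", "nú", "kò", "ú", "βú"]
        ]

    def test_deer_word_types(self):
        assert [s.type_label for s in Word("nììβúg^w^à").syllables] == [
            "CVV", "CV", "CV"
        ]

    def test_non_glottal_cluster_is_phonotactic_error(self):
        with pytest.raises(PhonotacticError):
            syllabify(tokenize("àktà"))

    def test_long_vowel_with_glottal_coda_is_error(self):
        with pytest.raises(PhonotacticError):
            syllabify(tokenize("nììʔtà"))

    def test_word_final_glottal_coda_configurable(self):
        assert syllabify(tokenize("báʔ"))[0].type_label == "CVC"
        with pytest.raises(PhonotacticError):
            syllabify(tokenize("báʔ"), allow_final_glottal_coda=False)

    @pytest.mark.parametrize(
        "syll, label, moras",
        [("káʔ", "CVC", 2), ("nìì", "CVV", 2), ("ò", "V", 1),
         ("bá", "CV", 1), ("àh", "VC", 2), ("èè", "VV", 2)],
    )
    def test_classification_and_weight(self, syll, label, moras):
        (s,) = syllabify(tokenize(syll))
        assert (s.type_label, s.weight_moras) == (label, moras)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2**20))
    def test_classifier_agrees_with_template_oracle(self, seed):
        """Brute-force template matching over the six syllable shapes."""
        templates = {
            (False, False, False): "V", (True, False, False): "CV",
            (False, False, True): "VC", (True, False, True): "CVC",
            (False, True, False): "VV", (True, True, False): "CVV",
        }
        for word in generate_lexicon(25, seed=seed):
            for s in word.syllables:
                key = (s.onset is not None, s.nucleus.long, s.coda is not None)
                assert s.type_label == templates[key]
                assert s.weight_moras == (
                    2 if (s.nucleus.long or s.coda) else 1
                )


class TestVtoVSegmentation:
    @pytest.mark.parametrize(
        "word, contents, types",
        [
            ("ʤìíʔ^j^ò", ["ì", "íʔ^j^", "ò"], ["V", "VC", "V"]),
            ("nèèpáh^j^ù", ["èèp", "áh^j^", "ù"], ["VVC", "VC", "V"]),
            ("òʔʣíβà", ["òʔʣ", "íβ", "à"], ["VCC", "VC", "V"]),
        ],
    )
    def test_proper_name_intervals(self, word, contents, types):
        _, ivs = segment_v_to_v(word)
        assert [nfc(str(iv)) for iv in ivs] == [nfc(c) for c in contents]
        assert [iv.type_label for iv in ivs] == types

    def test_fig3_phrase_segmentation(self):
        anacrusis, ivs = segment_v_to_v(FIG3)
        assert [p.symbol for p in anacrusis] == ["k"]
        assert [nfc(str(iv)) for iv in ivs] == [
            nfc(x) for x in
            ["áʔg", "ún", "úk", "ò", "úβ", "ú", "ò", "áʔʦ", "àk", "ún", "è"]
        ]
        assert [iv.type_label for iv in ivs] == [
            "VCC", "VC", "VC", "V", "VC", "V", "V", "VCC", "VC", "VC", "V"
        ]

    def test_second_interval_distinguishes_minimal_verb_pair(self):
        _, a = segment_v_to_v("mèg^w^ák^j^ùtéʔíhk^j^àkì")
        _, b = segment_v_to_v("mèkóóβàtéʔíhk^j^àkì")
        assert a[1].type_label == "VC" and nfc(str(a[1])) == nfc("ák^j^")
        assert b[1].type_label == "VVC" and nfc(str(b[1])) == nfc("óóβ")

    def test_cross_word_interval_flagged(self):
        _, ivs = segment_v_to_v("bàh tá")
        # word-final coda h plus next word's onset t -> VCC across words
        assert ivs[0].type_label == "VCC" and ivs[0].crosses_word_boundary

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**20))
    def test_partition_and_count_invariants(self, seed):
        """|syllables| = |intervals| = |nuclei|; every phoneme lands in
        exactly one syllable and one interval (or the anacrusis)."""
        words = generate_lexicon(6, seed=seed)
        phrase = Phrase(words=tuple(words))
        anacrusis, ivs = segment_v_to_v(phrase)
        sylls = phrase.syllables
        nuclei = [p for w in words for p in w.phonemes if p.is_vowel]
        assert len(sylls) == len(ivs) == len(nuclei)
        from_sylls = [p for s in sylls for p in s.phonemes]
        from_ivs = list(anacrusis) + [
            p for iv in ivs for p in (iv.nucleus, *iv.consonants)
        ]
        flat = [p for w in words for p in w.phonemes]
        assert from_sylls == flat
        assert from_ivs == flat


class TestTonePhonotactics:
    @pytest.mark.parametrize(
        "word, pattern",
        [("nììβúg^w^à", "LHL"), ("ʤìíʔ^j^ò", "LHL"), ("bá", "H"),
         ("tùùtáβààbè", "LHLL")],
    )
    def test_tone_pattern_one_tone_per_syllable(self, word, pattern):
        assert str(tone_pattern(word)) == pattern

    @pytest.mark.parametrize(
        "tones, position, n_violations",
        [
            ("LLH", "medial", 1),   # LL not at a tone-phrase end
            ("HLL", "final", 0),
            ("HHH", "final", 1),    # must end L phrase-finally
            ("LLL", "final", 1),    # leading LL is not final
            ("LHH", "medial", 0),
            ("HL", "medial", 1),
        ],
    )
    def test_rule_violations(self, tones, position, n_violations):
        pat = TonePattern(tuple(tones), position)
        assert len(validate_tones(pat, position)) == n_violations

    def test_trisyllabic_licit_sets_match_attested(self):
        assert enumerate_licit_tone_patterns(3, "medial") == {
            "HHH", "HLH", "LHH"
        }
        assert enumerate_licit_tone_patterns(3, "final") == {
            "HLL", "HHL", "LHL"
        }

    def test_monosyllables_and_errors(self):
        assert enumerate_licit_tone_patterns(1, "medial") == {"H"}
        assert enumerate_licit_tone_patterns(1, "final") == {"L"}
        with pytest.raises(ValueError):
            enumerate_licit_tone_patterns(0, "medial")

    @pytest.mark.parametrize("n", range(1, 9))
    @pytest.mark.parametrize("position", ["medial", "final"])
    def test_enumeration_equals_brute_force_oracle(self, n, position):
        """Independent restatement of the two rules, checked exhaustively."""
        def ok(seq):
            if position == "medial" and seq[-1] != "H":
                return False
            if position == "final" and seq[-1] != "L":
                return False
            for i in range(len(seq) - 1):
                if seq[i] == seq[i + 1] == "L":
                    if not (position == "final" and i == len(seq) - 2):
                        return False
            return True

        oracle = {"".join(s) for s in product("HL", repeat=n) if ok(s)}
        assert enumerate_licit_tone_patterns(n, position) == oracle
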