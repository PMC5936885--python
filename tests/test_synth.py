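"""Generator validity, determinism and noise-free exactness."""

import numpy as np
import pandas as pd
import pytest

from manguare.beats import DrummedMessage, align_beats, classify_beat_tone
from manguare.phonology import tone_pattern, validate_tones
from manguare.stats import ModelSpec, compare_modalities, fit_model
from manguare.synth import (
    DEFAULT_DRUMMERS,
    DrummerProfile,
    DurationModel,
    generate_drummed_corpus,
    generate_lexicon,
    generate_modality_pairs,
    generate_spoken_corpus,
    generate_study_corpus,
    synthesize_audio,
)


class TestLexicon:
    def test_words_are_phonotactically_and_tonally_valid(self):
        for position in ("medial", "final"):
            for w in generate_lexicon(100, seed=1, position=position):
                assert w.syllables  # syllabifies without error
                pat = tone_pattern(w.phonemes, position=position)
                assert validate_tones(pat, position) == []

    def test_trisyllabic_medial_tone_patterns_licit(self):
        words = generate_lexicon(
            50, seed=2, position="medial", syllable_count_weights={3: 1.0}
        )
        patterns = {w.tone_pattern_str for w in words}
        assert patterns <= {"HHH", "HLH", "LHH"}

    def test_injected_fixtures_and_errors(self):
        words = generate_lexicon(5, seed=3, include_words=["nììβúg^w^à"])
        assert words[0].transcription == "nììβúg^w^à" and len(words) == 5
        with pytest.raises(ValueError):
            generate_lexicon(0, seed=3)

    def test_determinism(self):
        a = generate_lexicon(30, seed=9)
        b = generate_lexicon(30, seed=9)
        assert [w.transcription for w in a] == [w.transcription for w in b]


class TestDrummedCorpus:
    def test_determinism_bit_identical(self):
        c1 = generate_study_corpus(seed=4, n_messages=20)
        c2 = generate_study_corpus(seed=4, n_messages=20)
        pd.testing.assert_frame_equal(c1.frame(), c2.frame())
        t1 = [b.time_s for m in c1.messages for b in m.beats]
        t2 = [b.time_s for m in c2.messages for b in m.beats]
        assert t1 == t2

    def test_noise_free_means_are_exact(self):
        model = DurationModel(noise_sd_s=0.0)
        corpus = generate_study_corpus(
            seed=5, n_messages=40, duration_model=model, slip_rate=0.0
        )
        df = corpus.frame()
        for d in DEFAULT_DRUMMERS:
            sub = df[df["drummer_id"] == d.id]
            for label, base in model.base_s.items():
                cell = sub[sub["vtov_label"] == label]["duration_s"]
                if len(cell):
                    expected = d.rate * base + d.offset_s
                    assert cell.to_numpy() == pytest.approx(
                        expected, abs=1e-9
                    )

    def test_slip_rate_one_rejects_every_message(self):
        corpus = generate_study_corpus(seed=6, n_messages=15, slip_rate=1.0)
        assert corpus.messages == []
        assert len(corpus.slipped) == 15
        for beats, phrase, drummer in corpus.slipped:
            assert not isinstance(
                align_beats(beats, phrase, drummer), DrummedMessage
            )

    def test_base_durations_must_increase(self):
        with pytest.raises(ValueError):
            DurationModel(base_s={"V": 0.32, "VC": 0.32, "VVC": 0.34,
                                  "VCC": 0.36})
        with pytest.raises(ValueError):
            DrummerProfile(id="x", rate=0.0)


class TestAudio:
    @pytest.mark.parametrize("tone, freq", [("H", 140.0), ("L", 95.0)])
    def test_single_beat_spectral_peak(self, tone, freq):
        table = pd.DataFrame({"time_s": [0.05], "tone_label": [tone]})
        audio, sr = synthesize_audio(table)
        res = classify_beat_tone(audio[int(0.05 * sr):], sr)
        assert res.pitch_hz == pytest.approx(freq, abs=3.0)
        assert res.label == tone

    def test_empty_table_is_silence_of_requested_duration(self):
        audio, sr = synthesize_audio(
            pd.DataFrame({"time_s": [], "tone_label": []}), duration_s=0.5
        )
        assert audio.size == int(0.5 * sr) and not audio.any()

    def test_close_beats_warn_about_overlap(self):
        table = pd.DataFrame(
            {"time_s": [0.1, 0.13], "tone_label": ["H", "H"]}
        )
        with pytest.warns(UserWarning):
            synthesize_audio(table)

    def test_audio_determinism(self):
        table = pd.DataFrame({"time_s": [0.1, 0.5], "tone_label": ["H", "L"]})
        a1, _ = synthesize_audio(table, seed=7, snr_db=20)
        a2, _ = synthesize_audio(table, seed=7, snr_db=20)
        assert np.array_equal(a1, a2)


class TestSpokenCorpus:
    def test_noise_free_modality_correspondence_is_perfect(self):
        words = generate_lexicon(
            20, seed=8, syllable_count_weights={3: 0.5, 4: 0.5}
        )
        pairs = generate_modality_pairs(words, noise_sd_s=0.0, seed=8)
        report = compare_modalities(pairs)
        assert report.fraction_corresponding == 1.0

    def test_speechtype_term_significant_when_scale_differs(self):
        model = DurationModel(spoken_scale=0.5)
        medial = generate_lexicon(30, seed=10, position="medial")
        final = generate_lexicon(10, seed=11, position="final")
        lex = {"medial": medial, "final": final}
        drummed = generate_drummed_corpus(
            lex, n_messages=60, seed=12, duration_model=model
        ).frame()
        spoken = generate_spoken_corpus(
            lex, n_utterances=120, seed=13, duration_model=model
        ).frame()
        df = pd.concat([drummed, spoken], ignore_index=True)
        fitted = fit_model(df, ModelSpec(unit="vtov",
                                         include_speechtype=True))
        assert fitted.anova.loc["SPEECHTYPE", "p_value"] < 1e-10
        # three-way sequential layout mirrors the published table order
        assert list(fitted.anova.index[:3]) == ["SPEECHTYPE", "DRUMMER",
                                                "TYPE"]

    def test_modality_correspondence_usually_perfect_at_5ms_noise(self):
        """With 5 ms noise and the shared 20 ms class spacing, all 14
        paired words correspond in at least 90% of runs."""
        n_runs, perfect = 30, 0
        for i in range(n_runs):
            words = generate_lexicon(
                14, seed=7000 + i,
                syllable_count_weights={3: 0.4, 4: 0.4, 5: 0.2},
            )
            pairs = generate_modality_pairs(words, noise_sd_s=0.005,
                                            seed=7500 + i)
            perfect += compare_modalities(pairs).fraction_corresponding == 1.0
        assert perfect >= 0.90 * n_runs

    def test_spoken_determinism(self):
        lex = generate_lexicon(10, seed=14, position="final")
        c1 = generate_spoken_corpus(lex, n_utterances=10, seed=15)
        c2 = generate_spoken_corpus(lex, n_utterances=10, seed=15)
        for (p1, o1, s1), (p2, o2, s2) in zip(c1.utterances, c2.utterances):
            assert str(p1) == str(p2) and s1 == s2
            assert np.array_equal(o1, o2)
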