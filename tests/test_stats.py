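"""Linear models, simultaneous contrasts, scales and consistency scoring."""

import warnings

import numpy as np
import pandas as pd
import pytest

from manguare.stats import (
    ContrastResult,
    ContrastSet,
    ModelSpec,
    backward_select,
    compare_modalities,
    consistency_score,
    derive_scale,
    fit_model,
    pairwise_contrasts,
    rank_sum_test,
)


def _frame(durations, types, drummers, speech="drummed"):
    n = len(durations)
    return pd.DataFrame(
        {
            "duration_s": durations,
            "vtov_label": types,
            "syllable_label": "CV",
            "mora_label": 1,
            "vlen_label": "short",
            "drummer_id": drummers,
            "speech_type": speech,
            "intra_word": True,
        }
    )


def _toy_2x2(n=5, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    means = {("1", "V"): 0.30, ("1", "VC"): 0.33,
             ("2", "V"): 0.35, ("2", "VC"): 0.41}
    for (d, t), mu in means.items():
        rows.append(_frame(rng.normal(mu, 0.01, n), t, d))
    return pd.concat(rows, ignore_index=True)


class TestFitModel:
    def test_matches_hand_computed_balanced_anova(self):
        """Independent oracle: textbook balanced two-way ANOVA formulas."""
        df = _toy_2x2(n=6, seed=1)
        y = df["duration_s"].to_numpy()
        a = df["drummer_id"].to_numpy()
        b = df["vtov_label"].to_numpy()
        grand = y.mean()
        ss_a = sum(
            (y[a == lv]).size * (y[a == lv].mean() - grand) ** 2
            for lv in np.unique(a)
        )
        # sequential: B after A equals its balanced main-effect SS
        ss_b = sum(
            (y[b == lv]).size * (y[b == lv].mean() - grand) ** 2
            for lv in np.unique(b)
        )
        ss_ab = sum(
            (y[(a == la) & (b == lb)]).size
            * (y[(a == la) & (b == lb)].mean()
               - y[a == la].mean() - y[b == lb].mean() + grand) ** 2
            for la in np.unique(a) for lb in np.unique(b)
        )
        ss_e = sum(
            ((y[(a == la) & (b == lb)]
              - y[(a == la) & (b == lb)].mean()) ** 2).sum()
            for la in np.unique(a) for lb in np.unique(b)
        )
        fitted = fit_model(df, ModelSpec(unit="vtov"))
        tab = fitted.anova
        assert tab.loc["DRUMMER", "sum_sq"] == pytest.approx(ss_a, abs=1e-12)
        assert tab.loc["TYPE", "sum_sq"] == pytest.approx(ss_b, abs=1e-12)
        assert tab.loc["DRUMMER:TYPE", "sum_sq"] == pytest.approx(
            ss_ab, abs=1e-12
        )
        mse = ss_e / (len(y) - 4)
        for term, ss, df_t in [("DRUMMER", ss_a, 1), ("TYPE", ss_b, 1),
                               ("DRUMMER:TYPE", ss_ab, 1)]:
            assert tab.loc[term, "F"] == pytest.approx(
                (ss / df_t) / mse, rel=1e-10
            )

    def test_sequential_ss_sum_to_total_and_adj_r2_bound(
        self, small_corpus_frame
    ):
        fitted = fit_model(small_corpus_frame, ModelSpec(unit="vtov"))
        assert fitted.anova["sum_sq"].sum() == pytest.approx(
            fitted.result.centered_tss, rel=1e-10
        )
        assert fitted.adj_r2 <= fitted.r2

    def test_constant_response_has_zero_effect_ss(self):
        df = _frame([0.3] * 40, ["V", "V", "VC", "VC"] * 10,
                    ["1", "2", "1", "2"] * 10)
        fitted = fit_model(df, ModelSpec(unit="vtov"))
        assert fitted.anova["sum_sq"].sum() == pytest.approx(0.0)
        assert fitted.adj_r2 <= 0

    def test_single_drummer_level_dropped_with_warning(self):
        df = _frame(np.linspace(0.3, 0.4, 40), ["V", "VC"] * 20, "1")
        with pytest.warns(UserWarning, match="DRUMMER"):
            fitted = fit_model(df, ModelSpec(unit="vtov"))
        assert "DRUMMER" not in fitted.formula


class TestContrasts:
    def test_family_sizes(self, small_corpus_frame):
        """Six syllable types over two drummers give 30 comparisons; four
        V-to-V types give 12."""
        syl = pairwise_contrasts(
            fit_model(small_corpus_frame, ModelSpec(unit="syllable"))
        )
        vtov = pairwise_contrasts(
            fit_model(small_corpus_frame, ModelSpec(unit="vtov"))
        )
        assert len(syl) == 30
        assert len(vtov) == 12

    def test_adjusted_p_not_below_raw_and_methods_agree(
        self, small_corpus_frame
    ):
        fitted = fit_model(small_corpus_frame, ModelSpec(unit="vtov"))
        maxt = pairwise_contrasts(fitted, method="max-t", seed=1)
        holm = pairwise_contrasts(fitted, method="holm")
        for r in maxt.results + holm.results:
            assert r.p_adjusted >= r.p_raw
        # well-separated case: both procedures reach the same verdicts
        verdicts = lambda cs: [r.significant for r in cs.results]
        assert verdicts(maxt) == verdicts(holm)

    def test_pooled_contrasts(self, small_corpus_frame):
        fitted = fit_model(small_corpus_frame, ModelSpec(unit="vtov"))
        pooled = pairwise_contrasts(fitted, within="pooled")
        assert len(pooled) == 6
        assert {r.group for r in pooled.results} == {"pooled"}


def _contrast_set(types, means, significant_pairs, group="1",
                  estimates=None):
    results = []
    from itertools import combinations

    for a, b in combinations(types, 2):
        sig = frozenset((a, b)) in {frozenset(p) for p in significant_pairs}
        est = (estimates or {}).get((a, b), means[a] - means[b])
        results.append(
            ContrastResult(group=group, type_a=a, type_b=b, estimate=est,
                           se=0.001, t=est / 0.001,
                           p_raw=0.001 if sig else 0.5,
                           p_adjusted=0.01 if sig else 0.9,
                           significant=sig)
        )
    cell_means = {(group, t): m for t, m in means.items()}
    return ContrastSet(results=results, cell_means=cell_means,
                       alpha=0.05, method="max-t")


class TestScale:
    def test_all_significant_gives_singleton_classes(self):
        types = ["V", "VC", "VVC", "VCC"]
        means = {"V": 0.30, "VC": 0.32, "VVC": 0.34, "VCC": 0.36}
        from itertools import combinations

        cs = _contrast_set(types, means, list(combinations(types, 2)))
        scale = derive_scale(cs)
        assert str(scale) == "V < VC < VVC < VCC"
        assert scale.singleton and not scale.non_transitive

    def test_no_significance_gives_single_class(self):
        means = {"V": 0.30, "VC": 0.30, "VVC": 0.30, "VCC": 0.30}
        cs = _contrast_set(list(means), means, [])
        scale = derive_scale(cs)
        assert len(scale.classes) == 1
        assert set(scale.classes[0]) == set(means)

    def test_partial_merge_formats_braces(self):
        means = {"CV": 0.30, "V": 0.32, "CVV": 0.34, "VC": 0.36,
                 "CVC": 0.361, "VV": 0.3605}
        sig = [("CV", "V"), ("V", "CVV"), ("CVV", "VV"), ("CVV", "CVC"),
               ("CVV", "VC"), ("CV", "CVV"), ("CV", "VV"), ("CV", "CVC"),
               ("CV", "VC"), ("V", "VV"), ("V", "CVC"), ("V", "VC")]
        cs = _contrast_set(list(means), means, sig)
        scale = derive_scale(cs)
        # merged class members listed in mean order
        assert str(scale) == "CV < V < CVV < {VC, VV, CVC}"
        assert not scale.non_transitive

    def test_non_transitive_pattern_flagged_not_resolved(self):
        means = {"V": 0.30, "VC": 0.31, "VVC": 0.32}
        cs = _contrast_set(list(means), means, [("V", "VVC")])
        scale = derive_scale(cs)
        assert scale.non_transitive
        assert len(scale.classes) == 1  # merges reported, ties flagged

    def test_group_must_be_chosen_when_ambiguous(self, small_corpus_frame):
        fitted = fit_model(small_corpus_frame, ModelSpec(unit="vtov"))
        cs = pairwise_contrasts(fitted, seed=3)
        with pytest.raises(ValueError):
            derive_scale(cs)
        assert derive_scale(cs, group="1").classes


class TestConsistency:
    TYPES = ["V", "CV", "VC", "CVC", "VV", "CVV"]

    def test_same_class_pairs_must_not_differ(self):
        means = {t: 0.3 for t in self.TYPES}
        means["VV"] = 0.34
        cs = _contrast_set(self.TYPES, means, [("VC", "VV")])
        rep = consistency_score(cs, "mora")
        verdict = {
            (a, b): v for _, a, b, v in rep.verdicts
        }[("VC", "VV")]
        assert verdict == "differ-but-shouldn't"

    def test_vowel_length_flags_v_vs_vc_difference(self):
        means = {t: 0.3 for t in self.TYPES}
        means["VC"] = 0.36
        cs = _contrast_set(self.TYPES, means, [("V", "VC")])
        rep = consistency_score(cs, "vowel-length")
        verdict = {(a, b): v for _, a, b, v in rep.verdicts}[("V", "VC")]
        assert verdict == "differ-but-shouldn't"

    def test_wrong_direction_detected(self):
        means = {t: 0.3 for t in self.TYPES}
        means["V"] = 0.36  # V longer than VV although lighter
        cs = _contrast_set(self.TYPES, means, [("V", "VV")])
        rep = consistency_score(cs, "vowel-length")
        verdict = {(a, b): v for _, a, b, v in rep.verdicts}[("V", "VV")]
        assert verdict == "wrong-direction"

    def test_fully_coherent_pattern_scores_zero(self):
        means = {"V": 0.30, "CV": 0.30, "VC": 0.34, "CVC": 0.34,
                 "VV": 0.34, "CVV": 0.34}
        heavy = {"VC", "CVC", "VV", "CVV"}
        sig = [(a, b) for a in means for b in means
               if a < b and (a in heavy) != (b in heavy)]
        cs = _contrast_set(self.TYPES, means, sig)
        rep = consistency_score(cs, "mora")
        assert rep.inconsistent == 0
        assert rep.total == 15


class TestBackwardSelection:
    def test_interaction_retained_under_interaction_truth(self):
        """Per-drummer rate multipliers induce a type×drummer interaction,
        detectable at the study-scale corpus of ~7,000 durations."""
        from manguare.synth import generate_study_corpus

        df = generate_study_corpus(seed=21).frame()
        fitted, log = backward_select(df, ModelSpec(unit="vtov"))
        assert "DRUMMER:TYPE" in fitted.formula
        assert any(s.term == "DRUMMER:TYPE" and not s.dropped for s in log)

    def test_interaction_dropped_under_additive_truth(self):
        """Monte Carlo: with additive truth the interaction survives only
        at roughly the nominal type-I rate."""
        rng = np.random.default_rng(99)
        base = {"V": 0.30, "VC": 0.32, "VVC": 0.34, "VCC": 0.36}
        offset = {"1": 0.0, "2": 0.02}
        n_runs, dropped = 200, 0
        for _ in range(n_runs):
            rows = []
            for d in ("1", "2"):
                for t, b in base.items():
                    rows.append(_frame(
                        rng.normal(b + offset[d], 0.015, 50), t, d
                    ))
            df = pd.concat(rows, ignore_index=True)
            fitted, _ = backward_select(df, ModelSpec(unit="vtov"))
            dropped += "DRUMMER:TYPE" not in fitted.formula
        assert dropped >= 0.90 * n_runs


class TestRankSum:
    def test_identical_samples_not_significant(self):
        stat, p = rank_sum_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_complete_separation_gives_zero_u(self):
        stat, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert stat == 0.0

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_power_on_shifted_exponentials(self):
        """20 ms shift between exponential samples of n=100: detected at
        alpha=0.05 in at least 95% of 200 runs."""
        rng = np.random.default_rng(7)
        hits = 0
        n_runs = 200
        for _ in range(n_runs):
            a = rng.exponential(0.020, 100)
            b = 0.020 + rng.exponential(0.020, 100)
            hits += rank_sum_test(a, b)[1] < 0.05
        assert hits >= 0.95 * n_runs


class TestCompareModalities:
    def test_agreeing_orders_correspond(self):
        rep = compare_modalities(
            {
                "w1": {"drummed": [0.34, 0.32, 0.36, 0.32],
                       "spoken": [0.17, 0.16, 0.18, 0.16]},
                "w2": {"drummed": [0.30], "spoken": [0.15]},
            }
        )
        assert rep.fraction_corresponding == 1.0

    def test_disagreeing_order_detected(self):
        rep = compare_modalities(
            {"w": {"drummed": [0.30, 0.36], "spoken": [0.18, 0.15]}}
        )
        assert rep.fraction_corresponding == 0.0

    def test_count_mismatch_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            rep = compare_modalities(
                {"w": {"drummed": [0.3, 0.4], "spoken": [0.15]}}
            )
        assert rep.skipped == ("w",)
        assert np.isnan(rep.fraction_corresponding)
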