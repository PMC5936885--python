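"""Linear models and simultaneous inference for interbeat durations.

The central question — which rhythmic unit do the drums encode? — is cast as
a model comparison.  Interbeat duration (IBD) is regressed on a unit-type
factor under each hypothesis (V-to-V interval type with four testable
levels, or syllable type with six), always crossed with a fixed DRUMMER
factor (with only two drummers, drummer is a fixed effect), and optionally
with SPEECHTYPE (drummed vs oral) when spoken vowel-onset intervals enter
the comparison.  Models are summarised with sequential (type I) ANOVA
tables, reduced by backward selection with nested F-tests, and compared by
adjusted R².

Within each model, all pairwise differences between unit types are tested
simultaneously.  Family-wise error is controlled at α by a single-step
max-|t| adjustment: the joint normal approximation of the contrast
estimates is sampled (Monte Carlo, seeded) to obtain the null distribution
of the largest absolute statistic; Holm's step-down procedure is available
as a deterministic fallback.  The significant contrasts induce a duration
scale — an ordering of unit types into equivalence classes — and each
competing hypothesis (mora count, vowel length) is scored by how many
pairwise verdicts it predicts correctly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from patsy import build_design_matrices
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .beats import IBDObservation, observations_to_frame

__all__ = [
    "ModelSpec",
    "FittedIBDModel",
    "SelectionStep",
    "ContrastResult",
    "ContrastSet",
    "ScaleOrdering",
    "ConsistencyReport",
    "ModalityReport",
    "VTOV_ORDER",
    "SYLLABLE_ORDER",
    "fit_model",
    "backward_select",
    "pairwise_contrasts",
    "derive_scale",
    "consistency_score",
    "rank_sum_test",
    "compare_modalities",
]

VTOV_ORDER = ("V", "VC", "VVC", "VCC")
SYLLABLE_ORDER = ("V", "CV", "VC", "CVC", "VV", "CVV")

_UNIT_COLUMNS = {
    "vtov": ("vtov_label", VTOV_ORDER),
    "syllable": ("syllable_label", SYLLABLE_ORDER),
    "mora": ("mora_label", (1, 2)),
    "vlen": ("vlen_label", ("short", "long")),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which factors enter the IBD model, and in which sequential order.

    Entry order is DRUMMER → TYPE → interaction; with ``include_speechtype``
    SPEECHTYPE enters first and all interactions up to the three-way term
    are added.
    """

    unit: Literal["vtov", "syllable", "mora", "vlen"] = "vtov"
    include_drummer: bool = True
    include_speechtype: bool = False
    interactions: bool = True

    def factors(self) -> list[str]:
        out = []
        if self.include_speechtype:
            out.append("SPEECHTYPE")
        if self.include_drummer:
            out.append("DRUMMER")
        out.append("TYPE")
        return out

    def terms(self) -> list[tuple[str, ...]]:
        """Model terms in sequential (table row) order."""
        fac = self.factors()
        terms: list[tuple[str, ...]] = [(f,) for f in fac]
        if self.interactions:
            for k in range(2, len(fac) + 1):
                terms.extend(combinations(fac, k))
        return terms


def _prepare_frame(observations, spec: ModelSpec) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        df = observations.copy()
    else:
        df = observations_to_frame(list(observations))
    column, order = _UNIT_COLUMNS[spec.unit]
    out = pd.DataFrame({"duration_s": df["duration_s"].to_numpy(dtype=float)})
    observed = [lvl for lvl in order if lvl in set(df[column])]
    dropped = sorted(set(df[column]) - set(order), key=str)
    if dropped:
        warnings.warn(
            f"unit levels outside the {spec.unit} inventory dropped: "
            f"{dropped}", stacklevel=3
        )
    out["TYPE"] = pd.Categorical(df[column], categories=observed, ordered=True)
    out["DRUMMER"] = pd.Categorical(df["drummer_id"].astype(str))
    out["SPEECHTYPE"] = pd.Categorical(df["speech_type"].astype(str))
    out = out[out["TYPE"].notna()].reset_index(drop=True)
    return out


def _effective_spec(df: pd.DataFrame, spec: ModelSpec) -> ModelSpec:
    """Drop factors with a single observed level (with a warning)."""
    changed = {}
    if spec.include_drummer and df["DRUMMER"].nunique() < 2:
        warnings.warn(
            "DRUMMER has a single observed level and is dropped from the "
            "model", stacklevel=3
        )
        changed["include_drummer"] = False
    if spec.include_speechtype and df["SPEECHTYPE"].nunique() < 2:
        warnings.warn(
            "SPEECHTYPE has a single observed level and is dropped from the "
            "model", stacklevel=3
        )
        changed["include_speechtype"] = False
    if changed:
        spec = ModelSpec(
            unit=spec.unit,
            include_drummer=changed.get("include_drummer",
                                        spec.include_drummer),
            include_speechtype=changed.get("include_speechtype",
                                           spec.include_speechtype),
            interactions=spec.interactions,
        )
    return spec


def _formula(terms: Sequence[tuple[str, ...]]) -> str:
    rhs = " + ".join(":".join(t) for t in terms) if terms else "1"
    return f"duration_s ~ {rhs}"


@dataclass
class FittedIBDModel:
    """An OLS fit with its sequential ANOVA table and adjusted R²."""

    spec: ModelSpec
    formula: str
    result: object  # statsmodels RegressionResults
    anova: pd.DataFrame
    adj_r2: float
    data: pd.DataFrame = field(repr=False, default=None)

    @property
    def r2(self) -> float:
        sst = self.result.centered_tss
        return 1.0 - self.result.ssr / sst if sst > 0 else 0.0


def _adjusted_r2(result) -> float:
    n = int(result.nobs)
    p = int(result.df_model) + 1
    sst = result.centered_tss
    r2 = 1.0 - result.ssr / sst if sst > 0 else 0.0
    if n <= p:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p)


def _fit(df: pd.DataFrame, terms: Sequence[tuple[str, ...]]):
    res = ols(_formula(terms), data=df).fit()
    if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
        raise ValueError(
            "singular design: some factor-level combinations are empty"
        )
    return res


def fit_model(observations, spec: ModelSpec | None = None) -> FittedIBDModel:
    """Ordinary least squares on the (full) factorial design.

    The ANOVA table uses sequential sums of squares in the spec's term
    order, so rows match the conventional table layout; the mean-square
    column is SS/df.  Factors with a single observed level are dropped with
    a warning; an inestimable (singular) design raises ``ValueError``.
    """
    spec = spec or ModelSpec()
    df = _prepare_frame(observations, spec)
    if not len(df):
        raise ValueError("no observations to fit")
    spec = _effective_spec(df, spec)
    res = _fit(df, spec.terms())
    sst = res.centered_tss
    if sst > 0:
        table = anova_lm(res, typ=1)
    else:  # constant response: all effect SS are zero by definition
        terms = [":".join(t) for t in spec.terms()] + ["Residual"]
        table = pd.DataFrame(
            {"df": [np.nan] * len(terms), "sum_sq": 0.0,
             "F": np.nan, "PR(>F)": np.nan},
            index=terms,
        )
    table = table.rename(columns={"PR(>F)": "p_value"})
    table["mean_sq"] = table["sum_sq"] / table["df"]
    table = table[["df", "sum_sq", "mean_sq", "F", "p_value"]]
    return FittedIBDModel(
        spec=spec,
        formula=_formula(spec.terms()),
        result=res,
        anova=table,
        adj_r2=_adjusted_r2(res),
        data=df,
    )


@dataclass(frozen=True)
class SelectionStep:
    term: str
    f_value: float
    df_num: float
    df_den: float
    p_value: float
    dropped: bool


def backward_select(
    observations,
    spec: ModelSpec | None = None,
    alpha: float = 0.05,
) -> tuple[FittedIBDModel, list[SelectionStep]]:
    """Backward selection by nested F-tests at level ``alpha``.

    At each step the least significant *maximal* term (one not marginal to
    any retained higher-order term) is tested by comparing the nested
    models; it is dropped iff its F-test is non-significant.  Selection
    stops when every maximal term is significant.  Returns the retained
    model and the test log.
    """
    spec = spec or ModelSpec()
    df = _prepare_frame(observations, spec)
    spec = _effective_spec(df, spec)
    terms = list(spec.terms())
    log: list[SelectionStep] = []
    while True:
        full = _fit(df, terms)
        maximal = [
            t for t in terms
            if not any(set(t) < set(u) for u in terms)
        ]
        tests = []
        for t in maximal:
            reduced = _fit(df, [u for u in terms if u != t])
            cmp_tbl = anova_lm(reduced, full)
            f = float(cmp_tbl["F"].iloc[1])
            p = float(cmp_tbl["Pr(>F)"].iloc[1])
            tests.append((t, f, float(cmp_tbl["df_diff"].iloc[1]),
                          float(full.df_resid), p))
        tests.sort(key=lambda x: -x[4])
        worst = tests[0]
        drop = worst[4] >= alpha and len(terms) > 1
        log.append(SelectionStep(":".join(worst[0]), worst[1], worst[2],
                                 worst[3], worst[4], dropped=drop))
        for t, f, dfn, dfd, p in tests[1:]:
            log.append(SelectionStep(":".join(t), f, dfn, dfd, p,
                                     dropped=False))
        if not drop:
            break
        terms.remove(worst[0])
    res = _fit(df, terms)
    table = anova_lm(res, typ=1).rename(columns={"PR(>F)": "p_value"})
    table["mean_sq"] = table["sum_sq"] / table["df"]
    fitted = FittedIBDModel(
        spec=spec,
        formula=_formula(terms),
        result=res,
        anova=table[["df", "sum_sq", "mean_sq", "F", "p_value"]],
        adj_r2=_adjusted_r2(res),
        data=df,
    )
    return fitted, log


# ---------------------------------------------------------------------------
# Simultaneous pairwise contrasts


@dataclass(frozen=True)
class ContrastResult:
    """One pairwise comparison of unit-type means (within one drummer)."""

    group: str  # drummer id or "pooled"
    type_a: str
    type_b: str
    estimate: float
    se: float
    t: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass
class ContrastSet:
    """All pairwise contrasts with family-wise adjusted p-values."""

    results: list[ContrastResult]
    cell_means: dict[tuple[str, str], float]  # (group, type) -> mean (s)
    alpha: float
    method: str

    def __len__(self) -> int:
        return len(self.results)

    def for_group(self, group: str) -> list[ContrastResult]:
        return [r for r in self.results if r.group == group]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.results])


def _cell_design_row(fitted: FittedIBDModel, assignments: dict) -> np.ndarray:
    """Design row for one factor-level cell, averaging over absent factors."""
    di = fitted.result.model.data.design_info
    grids: list[dict] = [dict(assignments)]
    for fac in ("SPEECHTYPE",):
        if fac in fitted.spec.factors() and fac not in assignments:
            levels = list(fitted.data[fac].cat.categories)
            grids = [dict(g, **{fac: lv}) for g in grids for lv in levels]
    rows = []
    for g in grids:
        new = pd.DataFrame({k: [v] for k, v in g.items()})
        (x,) = build_design_matrices([di], new)
        rows.append(np.asarray(x)[0])
    return np.mean(rows, axis=0)


def pairwise_contrasts(
    fitted: FittedIBDModel,
    within: Literal["drummer", "pooled"] = "drummer",
    alpha: float = 0.05,
    method: Literal["max-t", "holm"] = "max-t",
    n_draws: int = 100_000,
    seed: int = 12345,
) -> ContrastSet:
    """All unordered pairs of unit-type levels, simultaneously tested.

    With ``within="drummer"`` each drummer contributes one family member per
    type pair; ``"pooled"`` averages the cell means over drummers first.
    ``max-t`` adjusts p-values by the Monte Carlo distribution of the
    largest |t| under the joint normal approximation of the contrast
    estimates (``n_draws`` draws, fixed ``seed``); ``holm`` is the
    deterministic step-down fallback.  Adjusted p-values are never smaller
    than raw ones.
    """
    df = fitted.data
    types = list(df["TYPE"].cat.categories)
    has_drummer = "DRUMMER" in fitted.spec.factors()
    drummers = list(df["DRUMMER"].cat.categories) if has_drummer else []
    if within == "drummer" and has_drummer:
        groups = [str(d) for d in drummers]
    else:
        groups = ["pooled"]

    def cell_row(group: str, typ: str) -> np.ndarray:
        if group == "pooled" and has_drummer:
            return np.mean(
                [_cell_design_row(fitted, {"DRUMMER": d, "TYPE": typ})
                 for d in drummers], axis=0
            )
        assignments = {"TYPE": typ}
        if has_drummer:
            assignments["DRUMMER"] = group
        return _cell_design_row(fitted, assignments)

    beta = np.asarray(fitted.result.params)
    covb = np.asarray(fitted.result.cov_params())
    df_resid = float(fitted.result.df_resid)

    labels: list[tuple[str, str, str]] = []
    L = []
    cell_means: dict[tuple[str, str], float] = {}
    for g in groups:
        for typ in types:
            cell_means[(g, typ)] = float(cell_row(g, typ) @ beta)
        for a, b in combinations(types, 2):
            labels.append((g, str(a), str(b)))
            L.append(cell_row(g, str(a)) - cell_row(g, str(b)))
    Lm = np.asarray(L)
    est = Lm @ beta
    cov = Lm @ covb @ Lm.T
    se = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
    tvals = est / se
    p_raw = 2 * sps.t.sf(np.abs(tvals), df_resid)

    if method == "max-t":
        corr = cov / np.outer(se, se)
        corr = (corr + corr.T) / 2 + 1e-10 * np.eye(len(se))
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(
            np.zeros(len(se)), corr, size=n_draws, method="cholesky"
        )
        # all statistics share the residual-variance estimate: scale the
        # normal draws by a common chi factor (multivariate t null)
        scale = np.sqrt(rng.chisquare(df_resid, size=n_draws) / df_resid)
        max_abs = np.sort(np.abs(draws).max(axis=1) / scale)
        # P(max|Z| >= |t_i|) via the empirical null
        idx = np.searchsorted(max_abs, np.abs(tvals), side="left")
        p_adj = (len(max_abs) - idx) / len(max_abs)
    elif method == "holm":
        p_adj = multipletests(p_raw, alpha=alpha, method="holm")[1]
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    p_adj = np.maximum(p_adj, p_raw)

    results = [
        ContrastResult(
            group=g, type_a=a, type_b=b,
            estimate=float(est[i]), se=float(se[i]), t=float(tvals[i]),
            p_raw=float(p_raw[i]), p_adjusted=float(p_adj[i]),
            significant=bool(p_adj[i] < alpha),
        )
        for i, (g, a, b) in enumerate(labels)
    ]
    return ContrastSet(results=results, cell_means=cell_means,
                       alpha=alpha, method=method)


# ---------------------------------------------------------------------------
# Duration scale and hypothesis consistency


@dataclass(frozen=True)
class ScaleOrdering:
    """Unit types ordered by mean IBD, merged into equivalence classes.

    ``non_transitive`` flags a significance pattern that cannot be
    represented as a clean ordered partition (some pair inside a merged
    class still tests significant); such patterns are reported, never
    silently resolved.
    """

    classes: tuple[tuple[str, ...], ...]
    class_means: tuple[float, ...]
    non_transitive: bool = False

    def __str__(self) -> str:
        parts = [
            c[0] if len(c) == 1 else "{" + ", ".join(c) + "}"
            for c in self.classes
        ]
        return " < ".join(parts)

    @property
    def singleton(self) -> bool:
        return all(len(c) == 1 for c in self.classes)


def derive_scale(
    contrasts: ContrastSet, group: str | None = None
) -> ScaleOrdering:
    """Order unit types by estimated mean and merge non-significant pairs.

    ``group`` selects one drummer's family (or "pooled"); defaults to the
    only group present.  Adjacent types (in mean order) whose contrast is
    non-significant join one equivalence class, transitively.
    """
    groups = sorted({r.group for r in contrasts.results})
    if group is None:
        if len(groups) != 1:
            raise ValueError(
                f"contrast set covers groups {groups}; pick one explicitly"
            )
        group = groups[0]
    rs = contrasts.for_group(group)
    means = {
        t: m for (g, t), m in contrasts.cell_means.items() if g == group
    }
    sig = {
        frozenset((r.type_a, r.type_b)): r.significant for r in rs
    }
    order = sorted(means, key=means.get)
    parent = {t: t for t in order}

    def find(t):
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for a, b in zip(order, order[1:]):
        if not sig[frozenset((a, b))]:
            parent[find(b)] = find(a)
    classes: dict[str, list[str]] = {}
    for t in order:
        classes.setdefault(find(t), []).append(t)
    cls = [tuple(v) for v in classes.values()]
    cls.sort(key=lambda c: np.mean([means[t] for t in c]))
    non_transitive = any(
        sig[frozenset((a, b))]
        for c in cls for a, b in combinations(c, 2)
    )
    return ScaleOrdering(
        classes=tuple(cls),
        class_means=tuple(float(np.mean([means[t] for t in c])) for c in cls),
        non_transitive=non_transitive,
    )


#: Predicted weight class per syllable type under each derived hypothesis.
_HYPOTHESIS_CLASSES = {
    "mora": {"V": 1, "CV": 1, "VC": 2, "CVC": 2, "VV": 2, "CVV": 2},
    "vowel-length": {"V": 1, "CV": 1, "VC": 1, "CVC": 1, "VV": 2, "CVV": 2},
}


@dataclass(frozen=True)
class ConsistencyReport:
    """How well a binary weight hypothesis predicts the pairwise verdicts."""

    hypothesis: str
    verdicts: tuple[tuple[str, str, str, str], ...]
    # (group, type_a, type_b, verdict)

    @property
    def total(self) -> int:
        return len(self.verdicts)

    @property
    def inconsistent(self) -> int:
        return sum(1 for *_, v in self.verdicts if v != "coherent")

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for *_, v in self.verdicts:
            out[v] = out.get(v, 0) + 1
        return out


def consistency_score(
    contrasts: ContrastSet, hypothesis: Literal["mora", "vowel-length"]
) -> ConsistencyReport:
    """Judge every syllable-type contrast against a two-class hypothesis.

    Same predicted class but significant → "differ-but-shouldn't"; different
    classes but non-significant → "should-differ-but-doesn't"; different
    classes, significant, but with the heavier class *shorter* →
    "wrong-direction"; otherwise coherent.
    """
    classes = _HYPOTHESIS_CLASSES[hypothesis]
    verdicts = []
    for r in contrasts.results:
        ca, cb = classes[r.type_a], classes[r.type_b]
        if ca == cb:
            verdict = "differ-but-shouldn't" if r.significant else "coherent"
        elif not r.significant:
            verdict = "should-differ-but-doesn't"
        else:
            # estimate is mean(a) - mean(b); heavier class must be longer
            heavier_is_a = ca > cb
            longer_is_a = r.estimate > 0
            verdict = "coherent" if heavier_is_a == longer_is_a else (
                "wrong-direction"
            )
        verdicts.append((r.group, r.type_a, r.type_b, verdict))
    return ConsistencyReport(hypothesis=hypothesis, verdicts=tuple(verdicts))


# ---------------------------------------------------------------------------
# Non-parametric tests and modality comparison


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon–Mann–Whitney rank-sum test.

    Returns ``(U, p)`` where U counts pairs in which the first sample wins.
    Used where sub-sample normality is untenable.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank-sum test requires two non-empty samples")
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ModalityReport:
    """Per-word agreement of drummed and spoken interval-duration orderings."""

    per_word: tuple[tuple[str, bool], ...]
    skipped: tuple[str, ...] = ()

    @property
    def fraction_corresponding(self) -> float:
        if not self.per_word:
            return float("nan")
        return sum(ok for _, ok in self.per_word) / len(self.per_word)


def compare_modalities(
    paired: Mapping[str, Mapping[str, Sequence[float]]]
) -> ModalityReport:
    """Check per-word rank-order correspondence across modalities.

    ``paired`` maps each word to its ``"drummed"`` and ``"spoken"`` interval
    durations (in utterance order), optionally with the interval ``"types"``.
    When types are given, the word's durations are first averaged per type
    and the *types* are ranked by duration — two intervals of the same type
    carry no expected relative order, so only between-type order is
    compared.  Without types, the raw duration rank orders are compared.  A
    word corresponds when the orders agree across modalities; one-interval
    (or one-type) words correspond trivially.  Words whose interval counts
    differ are skipped with a warning.
    """
    per_word = []
    skipped = []
    for word, d in paired.items():
        drummed = np.asarray(d["drummed"], dtype=float)
        spoken = np.asarray(d["spoken"], dtype=float)
        if drummed.size != spoken.size:
            warnings.warn(
                f"{word}: {drummed.size} drummed vs {spoken.size} spoken "
                "intervals; word skipped", stacklevel=2
            )
            skipped.append(word)
            continue
        types = d.get("types")
        if types is not None:
            types = np.asarray(types)
            levels = sorted(set(types.tolist()))
            drummed = np.array([drummed[types == t].mean() for t in levels])
            spoken = np.array([spoken[types == t].mean() for t in levels])
        ok = bool(
            np.array_equal(sps.rankdata(drummed), sps.rankdata(spoken))
        )
        per_word.append((word, ok))
    return ModalityReport(per_word=tuple(per_word), skipped=tuple(skipped))
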