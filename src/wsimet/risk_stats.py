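"""Metastasis-risk statistics over contingency tables of ordered predictors.

Implements the association toolkit used to relate tumor-level predictors
(AI prediction, Clark's level, diameter class, staging systems, risk-factor
counts) to metastasis outcome: unadjusted odds ratios with Woolf confidence
intervals, concordance (tie-corrected rank) AUROCs for ordinal predictors,
risk-factor counting models, reference-coded logistic regression, Pearson
correlation matrices and chi-square / Fisher association tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyCounts",
    "OddsRatioResult",
    "odds_ratio",
    "ordinal_auc",
    "build_rfm",
    "profiles_from_cohort",
    "fit_logistic",
    "pearson_correlation_matrix",
    "association_test",
    "table2_report",
]

# CI multiplier 1.96, the conventional two-sided 95% value the published
# intervals were computed with (the exact quantile 1.95996 reproduces some
# printed bounds one ulp low).
_Z95 = 1.96


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding, the convention of the printed tables
    (Python's built-in round is half-even: round(5.625, 2) == 5.62)."""
    import decimal

    d = decimal.Decimal(repr(float(x))).quantize(
        decimal.Decimal(1).scaleb(-ndigits), rounding=decimal.ROUND_HALF_UP)
    return float(d)


@dataclass(frozen=True)
class ContingencyCounts:
    """Case/control counts across the ordered levels of one predictor.

    ``levels`` are ordered from lowest to highest presumed risk;
    ``cases``/``controls`` hold the per-level counts. Tumors with an unknown
    value for the predictor are excluded before construction, so the totals
    are the per-variable denominators, not the full cohort sizes.
    """

    levels: tuple[str, ...]
    cases: tuple[int, ...]
    controls: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.levels) == len(self.cases) == len(self.controls)):
            raise ValueError("levels, cases and controls must have equal length")
        if any(c < 0 for c in self.cases) or any(c < 0 for c in self.controls):
            raise ValueError("counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return int(sum(self.cases))

    @property
    def n_controls(self) -> int:
        return int(sum(self.controls))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"level": self.levels, "cases": self.cases, "controls": self.controls}
        )


@dataclass(frozen=True)
class OddsRatioResult:
    """Unadjusted odds ratio with Woolf (log-method) 95% CI and Wald p-value.

    ``estimable`` is False when any cell of the 2x2 is zero, in which case
    all numeric fields are NaN (reported as not-estimable rather than
    applying a continuity correction).
    """

    or_value: float
    ci_low: float
    ci_high: float
    p_value: float
    estimable: bool = True

    def __str__(self) -> str:  # Table-style display, 2 d.p.
        if not self.estimable:
            return "NA"
        return (f"{round_half_up(self.or_value, 2):.2f} "
                f"({round_half_up(self.ci_low, 2):.2f}-"
                f"{round_half_up(self.ci_high, 2):.2f})")


def odds_ratio(a: int, b: int, c: int, d: int) -> OddsRatioResult:
    """Odds ratio (a*d)/(b*c) of a 2x2 table with Woolf 95% CI.

    Cell layout: ``a`` exposed cases, ``b`` unexposed cases, ``c`` exposed
    controls, ``d`` unexposed controls. A zero anywhere makes the OR (or its
    variance) undefined; such tables are flagged not-estimable.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if min(a, b, c, d) == 0:
        return OddsRatioResult(math.nan, math.nan, math.nan, math.nan, estimable=False)
    or_value = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_value)
    ci_low = math.exp(log_or - _Z95 * se)
    ci_high = math.exp(log_or + _Z95 * se)
    z = log_or / se
    p = 2 * stats.norm.sf(abs(z))
    return OddsRatioResult(or_value, ci_low, ci_high, float(p))


def ordinal_auc(case_counts, control_counts) -> float:
    """Concordance AUROC of an ordinal predictor from grouped counts.

    Equals the tie-corrected rank statistic (W + T/2) / (n1*n0), where W is
    the number of case-control pairs in which the case sits at a strictly
    higher level and T the number of tied pairs. This is the probability
    that a random case outranks a random control, ties counted half — the
    grouped-data Mann-Whitney formulation of the AUROC.
    """
    cases = np.asarray(case_counts, dtype=np.int64)
    controls = np.asarray(control_counts, dtype=np.int64)
    if cases.shape != controls.shape or cases.ndim != 1:
        raise ValueError("case and control counts must be 1-D and aligned")
    if (cases < 0).any() or (controls < 0).any():
        raise ValueError("counts must be non-negative")
    n1, n0 = int(cases.sum()), int(controls.sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need at least one case and one control")
    controls_below = np.concatenate(([0], np.cumsum(controls)[:-1]))
    w = float(np.sum(cases * controls_below))
    t = float(np.sum(cases * controls))
    return (w + t / 2.0) / (n1 * n0)


def build_rfm(profiles: pd.DataFrame, selected_factors: list[str],
              case_column: str = "is_case") -> ContingencyCounts:
    """Risk-factor counting model: tabulate tumors by number of risk factors.

    ``profiles`` holds one row per tumor with boolean risk-factor columns
    (NaN = missing) and a boolean ``case_column``. Tumors missing any
    selected factor are excluded from the model — the published models vary
    their denominators the same way. Returns counts over rf_count
    0..len(selected_factors).
    """
    if not selected_factors:
        raise ValueError("selected_factors must be non-empty")
    for f in selected_factors:
        if f not in profiles.columns:
            raise ValueError(f"unknown risk factor {f!r}")
    sub = profiles[selected_factors + [case_column]].dropna(subset=selected_factors)
    rf_count = sub[selected_factors].astype(bool).sum(axis=1)
    k = len(selected_factors)
    is_case = sub[case_column].astype(bool)
    cases = [int(((rf_count == i) & is_case).sum()) for i in range(k + 1)]
    controls = [int(((rf_count == i) & ~is_case).sum()) for i in range(k + 1)]
    return ContingencyCounts(tuple(str(i) for i in range(k + 1)),
                             tuple(cases), tuple(controls))


def profiles_from_cohort(table: pd.DataFrame,
                         ai_met=None) -> pd.DataFrame:
    """Per-tumor risk-factor profiles from a clinicopathological table.

    Maps the cohort table's categorical columns to the boolean risk flags
    used by the counting models (NaN where the underlying value is unknown
    or cannot be assessed): ``clark5``, ``diam_ge30``, ``high_grade``,
    ``pathologist_met`` and, when per-tumor AI predictions are supplied
    via ``ai_met`` (aligned boolean sequence), ``ai_met``. ``is_case``
    marks the rapid-metastasis cohort.
    """
    def flag(col, true_value, unknown_values):
        vals = table[col].astype(str)
        out = (vals == true_value).astype(float)
        out[vals.isin(unknown_values)] = np.nan
        return out

    profiles = pd.DataFrame({
        "clark5": flag("clark", "5", {"unknown"}),
        "diam_ge30": (table["diameter_class"].astype(str) == ">=30").astype(float),
        "high_grade": flag("grade", "3", {"unknown"}),
        "pathologist_met": flag("pathologist_pred", "met", {"cannot_assess"}),
        "is_case": table["cohort"].astype(str) == "rapid_met",
    }, index=table.index)
    if ai_met is not None:
        profiles.insert(0, "ai_met", np.asarray(ai_met, dtype=float))
    return profiles


def _expand_counts(counts: ContingencyCounts) -> tuple[np.ndarray, np.ndarray]:
    """Expand grouped counts to per-observation (outcome, level-index) vectors."""
    y, lvl = [], []
    for i, (nc, nk) in enumerate(zip(counts.cases, counts.controls)):
        y.extend([1] * nc + [0] * nk)
        lvl.extend([i] * (nc + nk))
    return np.asarray(y), np.asarray(lvl)


def fit_logistic(outcome, predictor, reference_level: str) -> pd.DataFrame:
    """Reference-coded logistic regression of a binary outcome on one
    categorical predictor.

    Fits by maximum likelihood (IRLS, via statsmodels GLM/binomial) with
    dummy coding against ``reference_level`` and returns one row per
    non-reference level with columns ``or_value, ci_low, ci_high, p_value,
    estimable``. For a single saturated categorical predictor the fitted
    per-level ORs coincide with the 2x2 cross-product ratios; levels whose
    2x2 against the reference contains a zero cell are completely separated
    and reported not-estimable.
    """
    import statsmodels.api as sm

    y = pd.Series(outcome).reset_index(drop=True).astype(float)
    x = pd.Series(predictor).reset_index(drop=True).astype(str)
    levels = [l for l in pd.unique(x) if l != reference_level]
    if reference_level not in set(x):
        raise ValueError(f"reference level {reference_level!r} absent from predictor")
    dummies = pd.get_dummies(x)[levels].astype(float)
    X = sm.add_constant(dummies)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation warnings handled per level below
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    rows = []
    for lev in levels:
        a = int(((x == lev) & (y == 1)).sum())
        c = int(((x == lev) & (y == 0)).sum())
        b = int(((x == reference_level) & (y == 1)).sum())
        d = int(((x == reference_level) & (y == 0)).sum())
        if min(a, b, c, d) == 0:  # separation against the reference
            rows.append({"level": lev, "or_value": math.nan, "ci_low": math.nan,
                         "ci_high": math.nan, "p_value": math.nan, "estimable": False})
            continue
        beta = float(fit.params[lev])
        se = float(fit.bse[lev])
        rows.append({
            "level": lev,
            "or_value": math.exp(beta),
            "ci_low": math.exp(beta - _Z95 * se),
            "ci_high": math.exp(beta + _Z95 * se),
            "p_value": float(fit.pvalues[lev]),
            "estimable": True,
        })
    return pd.DataFrame(rows).set_index("level")


def fit_logistic_counts(counts: ContingencyCounts,
                        reference_level: str | None = None) -> pd.DataFrame:
    """`fit_logistic` on grouped counts; reference defaults to the lowest level."""
    y, lvl = _expand_counts(counts)
    labels = np.asarray(counts.levels)[lvl]
    ref = counts.levels[0] if reference_level is None else reference_level
    return fit_logistic(y, labels, ref)


def pearson_correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation of numeric/ordinal-coded columns.

    Unknowns must already be NaN. Zero-variance columns produce NaN entries
    (flagged undefined) off the diagonal; the diagonal is 1 wherever the
    column has any observed value.
    """
    num = table.apply(pd.to_numeric, errors="coerce")
    corr = num.corr(method="pearson", min_periods=2)
    for col in corr.columns:
        if num[col].notna().any():
            corr.loc[col, col] = 1.0
    return corr


def association_test(table) -> tuple[float, str]:
    """Two-sided association test on a 2xk count table.

    Uses Fisher's exact test for 2x2 tables whose smallest expected cell
    does not exceed 5, otherwise the Pearson chi-square test (no continuity
    correction). Returns ``(p_value, test_name)``.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError("expected a 2xk table with k >= 2")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError("degenerate table: empty row or column")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if t.shape[1] == 2 and (expected <= 5).any():
        _, p = stats.fisher_exact(t, alternative="two-sided")
        return float(p), "fisher"
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(p), "chi2"


def table2_report(tables: dict[str, ContingencyCounts]) -> pd.DataFrame:
    """Per-variable risk report: ordinal AUROC plus per-level OR vs reference.

    The reference is the lowest (first) level of each variable. Output is
    one row per non-reference level with the variable's AUROC repeated, in
    the layout of the published risk-analysis table.
    """
    rows = []
    for name, counts in tables.items():
        auc = ordinal_auc(counts.cases, counts.controls)
        ref_case, ref_ctrl = counts.cases[0], counts.controls[0]
        for lev, ncase, nctrl in list(zip(counts.levels, counts.cases, counts.controls))[1:]:
            res = odds_ratio(ncase, ref_case, nctrl, ref_ctrl)
            rows.append({
                "variable": name, "level": lev, "cases": ncase, "controls": nctrl,
                "or_value": res.or_value, "ci_low": res.ci_low,
                "ci_high": res.ci_high, "p_value": res.p_value,
                "estimable": res.estimable, "auroc": auc,
            })
    return pd.DataFrame(rows)
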