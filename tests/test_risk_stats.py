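"""Odds ratios, ordinal concordance AUROCs, RFMs, logistic regression and
association tests, checked against hand computation, exact enumeration
oracles and the published table values."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wsimet import risk_stats as rs


def brute_force_auc(case_counts, control_counts):
    """All-pairs concordance oracle: expand counts and double-loop."""
    case_levels = [i for i, n in enumerate(case_counts) for _ in range(n)]
    control_levels = [i for i, n in enumerate(control_counts) for _ in range(n)]
    total = 0.0
    for a in case_levels:
        for b in control_levels:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(case_levels) * len(control_levels))


class TestOddsRatio:
    @pytest.mark.parametrize("cells,expected", [
        ((14, 8, 14, 45), 5.63),    # AI prediction (rounds half-up from 5.625)
        ((15, 4, 12, 44), 13.75),   # Clark level 5
        ((12, 2, 6, 22), 22.00),    # diameter >=30 vs <10
        ((13, 8, 10, 49), 7.96),    # invasion beyond fat
        ((9, 2, 3, 43), 64.50),     # conventional RFM, 2 risk factors
        ((13, 1, 7, 36), 66.86),    # BWH T2b vs T1
    ])
    def test_published_values(self, cells, expected):
        res = rs.odds_ratio(*cells)
        assert rs.round_half_up(res.or_value, 2) == pytest.approx(expected)
        assert res.ci_low < res.or_value < res.ci_high

    def test_unit_table_is_symmetric(self):
        res = rs.odds_ratio(1, 1, 1, 1)
        assert res.or_value == pytest.approx(1.0)
        assert res.ci_low < 1 < res.ci_high

    def test_zero_cell_not_estimable(self):
        res = rs.odds_ratio(8, 0, 33, 23)
        assert not res.estimable
        assert math.isnan(res.or_value)
        assert str(res) == "NA"

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            rs.odds_ratio(-1, 2, 3, 4)

    def test_reciprocal_identity(self, rng):
        for _ in range(25):
            a, b, c, d = rng.integers(1, 40, size=4)
            left = rs.odds_ratio(a, b, c, d).or_value
            right = rs.odds_ratio(b, a, d, c).or_value
            assert left * right == pytest.approx(1.0, rel=1e-12)

    def test_ai_ci_matches_published(self):
        res = rs.odds_ratio(14, 8, 14, 45)
        assert rs.round_half_up(res.ci_low, 2) == pytest.approx(1.96)
        assert rs.round_half_up(res.ci_high, 2) == pytest.approx(16.17)


class TestOrdinalAuc:
    @pytest.mark.parametrize("name,expected", [
        ("ai_rfm", 0.917),
        ("conventional_rfm", 0.862),
        ("diameter", 0.804),
        ("bwh", 0.818),
        ("clark", 0.788),
        ("pathologist_prediction", 0.694),
    ])
    def test_published_values(self, paper_fixtures, name, expected):
        t = paper_fixtures.tables[name]
        auc = rs.ordinal_auc(t.cases, t.controls)
        assert round(auc, 3) == pytest.approx(expected)

    def test_identical_distributions_give_half(self):
        assert rs.ordinal_auc([3, 5, 2], [6, 10, 4]) == pytest.approx(0.5)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            rs.ordinal_auc([0, 0], [1, 2])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 6))
            cases = rng.integers(0, 6, size=k)
            controls = rng.integers(0, 6, size=k)
            if cases.sum() == 0 or controls.sum() == 0:
                continue
            assert rs.ordinal_auc(cases, controls) == pytest.approx(
                brute_force_auc(cases, controls), abs=1e-12)

    def test_collapsing_single_class_levels_preserves_auc(self):
        # merging adjacent levels that jointly hold only one class cannot
        # change any case-control pair's ordering (case-case pairs do not
        # enter the statistic)
        cases = np.array([0, 4, 3, 2])
        controls = np.array([5, 0, 0, 1])
        merged_cases = np.array([0, 7, 2])      # merge levels 1 and 2
        merged_controls = np.array([5, 0, 1])
        assert rs.ordinal_auc(cases, controls) == pytest.approx(
            rs.ordinal_auc(merged_cases, merged_controls))


class TestRfm:
    def test_reproduces_published_ai_rfm_counts(self, paper_fixtures):
        # construct per-tumor profiles realizing the published per-level
        # counts, then re-tabulate through the counting model
        t = paper_fixtures.tables["ai_rfm"]
        rows = []
        for level, n_case, n_ctrl in zip(t.levels, t.cases, t.controls):
            k = int(level)
            flags = [True] * k + [False] * (3 - k)
            for _ in range(n_case):
                rows.append(dict(ai_met=flags[0], clark5=flags[1],
                                 diam_ge30=flags[2], is_case=True))
            for _ in range(n_ctrl):
                rows.append(dict(ai_met=flags[0], clark5=flags[1],
                                 diam_ge30=flags[2], is_case=False))
        profiles = pd.DataFrame(rows)
        counts = rs.build_rfm(profiles, ["ai_met", "clark5", "diam_ge30"])
        assert counts.cases == (0, 5, 9, 5)
        assert counts.controls == (32, 20, 4, 0)

    def test_missing_factor_rows_are_excluded(self):
        profiles = pd.DataFrame({
            "a": [True, np.nan, False], "b": [True, True, False],
            "is_case": [True, True, False]})
        counts = rs.build_rfm(profiles, ["a", "b"])
        assert counts.n_cases + counts.n_controls == 2

    def test_unknown_factor_rejected(self):
        profiles = pd.DataFrame({"a": [True], "is_case": [True]})
        with pytest.raises(ValueError):
            rs.build_rfm(profiles, ["nope"])

    def test_empty_factor_list_rejected(self):
        with pytest.raises(ValueError):
            rs.build_rfm(pd.DataFrame({"is_case": [True]}), [])

    def test_profiles_from_cohort_flags_and_missing(self):
        table = pd.DataFrame({
            "cohort": ["rapid_met", "non_met", "non_met"],
            "clark": ["5", "2-4", "unknown"],
            "diameter_class": [">=30", "<10", "20-29.9"],
            "grade": ["3", "1", "unknown"],
            "pathologist_pred": ["met", "non_met", "cannot_assess"],
        })
        prof = rs.profiles_from_cohort(table)
        assert prof.loc[0, "clark5"] == 1.0
        assert prof.loc[1, "clark5"] == 0.0
        assert np.isnan(prof.loc[2, "clark5"])
        assert np.isnan(prof.loc[2, "pathologist_met"])
        assert prof["is_case"].tolist() == [True, False, False]
        counts = rs.build_rfm(prof, ["clark5", "diam_ge30"])
        assert counts.n_cases == 1 and counts.n_controls == 1  # row 2 excluded
        assert counts.cases == (0, 0, 1)

    def test_all_false_profiles_pile_at_zero(self):
        profiles = pd.DataFrame({
            "a": [False] * 5, "b": [False] * 5, "is_case": [True] * 5})
        counts = rs.build_rfm(profiles, ["a", "b"])
        assert counts.cases == (5, 0, 0)


class TestLogistic:
    def test_diameter_or_matches_published(self, paper_fixtures):
        res = rs.fit_logistic_counts(paper_fixtures.tables["diameter"])
        assert rs.round_half_up(res.loc[">=30", "or_value"], 2) == pytest.approx(22.00)

    def test_ajcc_t3_or_matches_published(self, paper_fixtures):
        res = rs.fit_logistic_counts(paper_fixtures.tables["ajcc8"])
        assert rs.round_half_up(res.loc["T3", "or_value"], 2) == pytest.approx(36.67)

    def test_binary_predictor_equals_cross_product(self, paper_fixtures):
        t = paper_fixtures.tables["ai_prediction"]
        logit = rs.fit_logistic_counts(t).loc["met", "or_value"]
        woolf = rs.odds_ratio(t.cases[1], t.cases[0],
                              t.controls[1], t.controls[0]).or_value
        assert logit == pytest.approx(woolf, rel=1e-6)

    def test_null_predictor_ors_near_one(self, rng):
        n = 4000
        y = rng.integers(0, 2, size=n)
        x = rng.choice(["a", "b", "c"], size=n)
        res = rs.fit_logistic(y, x, "a")
        assert np.allclose(res["or_value"], 1.0, atol=0.25)

    def test_separated_level_flagged(self):
        counts = rs.ContingencyCounts(("lo", "hi"), (5, 4), (10, 0))
        res = rs.fit_logistic_counts(counts)
        assert not res.loc["hi", "estimable"]

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            rs.fit_logistic([0, 1], ["a", "b"], "z")


class TestCorrelationAndAssociation:
    def test_self_and_negated_correlation(self, rng):
        x = rng.normal(size=200)
        df = pd.DataFrame({"x": x, "neg": -x})
        corr = rs.pearson_correlation_matrix(df)
        assert corr.loc["x", "x"] == pytest.approx(1.0)
        assert corr.loc["x", "neg"] == pytest.approx(-1.0)

    def test_bivariate_normal_recovery(self, rng):
        n, rho = 10_000, 0.3
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        corr = rs.pearson_correlation_matrix(pd.DataFrame(z, columns=["u", "v"]))
        assert corr.loc["u", "v"] == pytest.approx(rho, abs=0.03)

    def test_zero_variance_column_flagged(self):
        corr = rs.pearson_correlation_matrix(
            pd.DataFrame({"c": [1.0, 1.0, 1.0], "x": [1.0, 2.0, 3.0]}))
        assert math.isnan(corr.loc["c", "x"])

    def test_balanced_table_p_one(self):
        p, test = rs.association_test([[10, 10], [10, 10]])
        assert p == pytest.approx(1.0)
        assert test == "chi2"

    def test_fisher_matches_hypergeometric_enumeration(self):
        # exact two-sided Fisher p: sum of hypergeometric probabilities
        # of all tables at most as probable as the observed one
        table = [[1, 9], [9, 1]]
        p, test = rs.association_test(table)
        assert test == "fisher"
        n1, n0, k = 10, 10, 10  # row sums and first-column sum
        probs = [stats.hypergeom.pmf(a, n1 + n0, n1, k) for a in range(11)]
        observed = stats.hypergeom.pmf(1, n1 + n0, n1, k)
        expected = sum(p_a for p_a in probs if p_a <= observed * (1 + 1e-9))
        assert p == pytest.approx(expected, rel=1e-9)

    def test_perineural_fixture_p_one(self, paper_fixtures):
        t = paper_fixtures.tables["perineural_invasion"]
        p, test = rs.association_test([list(t.cases), list(t.controls)])
        assert test == "fisher"
        assert round(p, 3) == pytest.approx(1.000)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            rs.association_test([[0, 0], [1, 2]])
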