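"""Statistics pipeline against hand-computed and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from abza.cohort_stats import (
    TwoByTwo,
    confusion_metrics,
    contingency_analysis,
    delong_auc_variance,
    fit_logistic,
    interrater_reliability,
    reproduce_printed_tables,
    roc_analysis,
    round_half_up,
    univariate_compare,
)
from abza.errors import ConstantScoreWarning, DegenerateTestError, SeparationError


def chi_square_oracle(table):
    """Textbook Pearson statistic: sum (O-E)^2 / E."""
    o = np.asarray(table, dtype=float)
    e = np.outer(o.sum(axis=1), o.sum(axis=0)) / o.sum()
    return float(((o - e) ** 2 / e).sum())


def concordance_oracle(scores, outcomes):
    """Brute-force AUC: concordant case-control pairs, ties count 1/2."""
    s = np.asarray(scores, float)
    y = np.asarray(outcomes)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_published_cohort_counts(self, published_counts):
        cm = confusion_metrics(TwoByTwo(**published_counts))
        assert round(cm.sensitivity, 3) == 0.757
        assert round(cm.specificity, 3) == 0.887
        assert round(cm.youden, 3) == 0.644
        assert cm.odds_ratio == pytest.approx(24.5)

    def test_perfect_classifier(self):
        cm = confusion_metrics(TwoByTwo(tp=5, fn=0, fp=0, tn=5))
        assert (cm.sensitivity, cm.specificity, cm.youden) == (1.0, 1.0, 1.0)
        assert "odds_ratio" in cm.undefined

    def test_zero_denominator_reported_as_undefined(self):
        cm = confusion_metrics(TwoByTwo(tp=0, fn=0, fp=3, tn=7))
        assert cm.sensitivity is None
        assert "sensitivity" in cm.undefined and "youden" in cm.undefined

    @given(st.integers(1, 20), st.integers(1, 20), st.integers(1, 20),
           st.integers(1, 20), st.integers(2, 9))
    def test_invariant_to_scaling_all_cells(self, tp, fn, fp, tn, k):
        a = confusion_metrics(TwoByTwo(tp, fn, fp, tn))
        b = confusion_metrics(TwoByTwo(k * tp, k * fn, k * fp, k * tn))
        assert b.sensitivity == pytest.approx(a.sensitivity)
        assert b.specificity == pytest.approx(a.specificity)
        assert b.youden == pytest.approx(a.youden)
        assert b.odds_ratio == pytest.approx(a.odds_ratio)


class TestUnivariate:
    def test_identical_groups_give_t_zero_p_one(self):
        vals = [55.0, 60, 62, 65, 68, 70, 72, 75]
        df = pd.DataFrame({"x": vals * 2, "mrs_90": [1] * 8 + [5] * 8})
        res = univariate_compare(df, "x")
        assert res.test_name == "t_test"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_collateral_outcome_table_chi_square(self, reconstructed_cohort):
        res = univariate_compare(reconstructed_cohort, "good_collateral")
        assert res.test_name == "chi_square"
        assert res.p < 0.001
        assert res.statistic == pytest.approx(
            chi_square_oracle([[28, 9], [8, 63]]))

    def test_balanced_small_table_routes_to_fisher(self):
        df = pd.DataFrame({"x": [True, False] * 2, "mrs_90": [1, 1, 5, 5]})
        res = univariate_compare(df, "x")
        assert res.test_name == "fisher_exact"
        assert res.p == pytest.approx(1.0)

    def test_constant_variable_rejected(self):
        df = pd.DataFrame({"x": [1.0] * 10, "mrs_90": [1] * 5 + [5] * 5})
        with pytest.raises(DegenerateTestError):
            univariate_compare(df, "x", kind="continuous")


class TestLogistic:
    def test_single_binary_covariate_equals_cross_ratio(self, reconstructed_cohort):
        res = fit_logistic(reconstructed_cohort, ["good_collateral"])
        fitted = res.term("good_collateral").odds_ratio
        assert fitted == pytest.approx(24.5, rel=1e-4)  # 4 significant figures

    def test_wald_ci_brackets_or(self, reconstructed_cohort):
        t = fit_logistic(reconstructed_cohort, ["good_collateral"]).term(
            "good_collateral")
        assert t.ci_low <= t.odds_ratio <= t.ci_high
        assert t.p < 0.001

    def test_single_class_outcome_rejected(self):
        df = pd.DataFrame({"x": [0.0, 1, 2, 3], "mrs_90": [1, 1, 2, 0]})
        with pytest.raises(SeparationError):
            fit_logistic(df, ["x"])

    def test_separated_data_rejected(self):
        df = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)],
                           "mrs_90": [5] * 20 + [1] * 20})
        with pytest.raises(SeparationError):
            fit_logistic(df, ["x"])

    def test_three_level_factor_reference_coding(self, rng):
        n = 400
        toast = rng.choice(["LAA", "CE", "other_unknown"], size=n)
        age = rng.normal(68, 9, n)
        p = 1 / (1 + np.exp(-(-0.5 + 0.8 * (toast == "CE"))))
        df = pd.DataFrame({
            "toast": toast, "age": age,
            "mrs_90": np.where(rng.random(n) < p, 1, 5),
        })
        res = fit_logistic(df, ["age", "toast"])
        names = [t.name for t in res.terms]
        assert "toast[CE]" in names and "toast[other_unknown]" in names
        assert "toast[LAA]" not in names  # LAA is the reference level
        assert "toast" in res.factor_pvalues


class TestROC:
    def test_constant_scores_auc_half_with_warning(self):
        with pytest.warns(ConstantScoreWarning):
            r = roc_analysis([3.0] * 10, [0, 1] * 5)
        assert r.auc == 0.5 and r.youden == 0.0

    def test_perfect_separation(self):
        r = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0 and r.youden == pytest.approx(1.0)
        assert 3 < r.cutoff < 10  # any midpoint between the groups
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_auc_equals_brute_force_concordance_with_ties(self):
        scores = [1, 2, 2, 3, 4, 5, 5, 6, 7, 8]
        outcomes = [0, 0, 1, 0, 0, 1, 1, 1, 0, 1]
        r = roc_analysis(scores, outcomes)
        assert r.auc == pytest.approx(concordance_oracle(scores, outcomes))

    def test_delong_variance_matches_reference_implementation(self):
        # frozen oracle: R pROC var(..., method="delong") on this fixture
        scores = np.array([1, 2, 2, 3, 4, 5, 5, 6, 7, 8], float)
        outcomes = np.array([0, 0, 1, 0, 0, 1, 1, 1, 0, 1])
        assert delong_auc_variance(scores, outcomes) == pytest.approx(0.0332)
        r = roc_analysis(scores, outcomes)
        assert r.auc == pytest.approx(0.74)
        assert r.auc_ci[0] == pytest.approx(0.3828775660, abs=1e-9)
        assert r.auc_ci[1] == 1.0

    def test_cutoff_sits_at_midpoint_between_observed_scores(self):
        r = roc_analysis([50.0, 55.0, 57.5, 58.1, 60.0, 70.0],
                         [0, 0, 0, 1, 1, 1])
        assert r.cutoff == pytest.approx((57.5 + 58.1) / 2)

    @given(st.data())
    def test_youden_identity_and_concordance_equivalence(self, data):
        n = data.draw(st.integers(6, 50))
        scores = data.draw(st.lists(st.integers(0, 8), min_size=n, max_size=n))
        outcomes = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda y: 0 < sum(y) < len(y)))
        if len(set(scores)) == 1:
            with pytest.warns(ConstantScoreWarning):
                r = roc_analysis(scores, outcomes)
        else:
            r = roc_analysis(scores, outcomes)
        assert r.youden == pytest.approx(r.sensitivity + r.specificity - 1,
                                         abs=1e-12)
        assert r.auc == pytest.approx(concordance_oracle(scores, outcomes))

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateTestError):
            roc_analysis([1, 2, 3], [1, 1, 1])


class TestContingency:
    def test_etiology_by_collateral_table(self):
        # grade>2 vs <=2 split by LAA/CE in the source cohort
        res = contingency_analysis([[10, 49], [23, 21]])
        assert res.p < 0.05
        assert res.statistic == pytest.approx(
            chi_square_oracle([[10, 49], [23, 21]]))

    def test_balanced_table_has_zero_statistic(self):
        res = contingency_analysis([[5, 5], [5, 5]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_maximal_association(self):
        res = contingency_analysis([[0, 10], [10, 0]])
        assert res.p < 1e-4

    def test_small_expected_counts_route_to_fisher(self):
        res = contingency_analysis([[1, 1], [1, 1]])
        assert res.test_name == "fisher_exact"
        assert res.p == pytest.approx(1.0)

    def test_empty_margin_rejected(self):
        with pytest.raises(DegenerateTestError):
            contingency_analysis([[0, 0], [5, 3]])

    @given(st.lists(st.lists(st.integers(1, 30), min_size=3, max_size=3),
                    min_size=3, max_size=3))
    def test_statistic_matches_textbook_oracle(self, table):
        res = contingency_analysis(table)
        assert res.statistic == pytest.approx(chi_square_oracle(table))


class TestInterrater:
    def test_identical_ratings_give_one_in_both_modes(self):
        v = [10.0, 35.0, 50.0, 62.0, 80.0, 88.0]
        assert interrater_reliability(v, v, "continuous_angle") == pytest.approx(1.0)
        g = [0, 1, 2, 3, 4, 4]
        assert interrater_reliability(g, g, "ordinal_grade") == pytest.approx(1.0)

    def test_constant_rater_gives_kappa_zero(self):
        assert interrater_reliability([2, 2, 2, 2], [0, 1, 3, 4],
                                      "ordinal_grade") == pytest.approx(0.0)

    def test_weighted_kappa_matches_hand_expanded_weights(self):
        a = np.array([0, 1, 2, 3, 4, 2])
        b = np.array([0, 2, 2, 3, 3, 1])
        # oracle: kappa_w = 1 - sum(w.O) / sum(w.E), w_ij = |i-j|
        labels = np.arange(5)
        obs = np.zeros((5, 5))
        for x, y in zip(a, b):
            obs[x, y] += 1
        obs /= obs.sum()
        exp = np.outer(obs.sum(axis=1), obs.sum(axis=0))
        w = np.abs(labels[:, None] - labels[None, :])
        oracle = 1.0 - (w * obs).sum() / (w * exp).sum()
        assert interrater_reliability(a, b, "ordinal_grade") == pytest.approx(
            oracle)

    def test_icc_matches_variance_component_oracle(self):
        a = np.array([10.0, 35.0, 52.0, 60.0, 81.0, 88.0])
        b = np.array([14.0, 30.0, 55.0, 63.0, 78.0, 90.0])
        n, k = len(a), 2
        data = np.c_[a, b]
        grand = data.mean()
        msr = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        sst = ((data - grand) ** 2).sum()
        mse = (sst - (n - 1) * msr / k * k - (k - 1) * msc / n * n) / (
            (n - 1) * (k - 1))
        oracle = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert interrater_reliability(a, b, "continuous_angle") == pytest.approx(
            oracle, abs=1e-9)

    def test_zero_variance_in_both_raters_rejected(self):
        with pytest.raises(DegenerateTestError):
            interrater_reliability([3, 3, 3], [3, 3, 3])


class TestReproduce:
    def test_all_published_numbers_reproduced(self):
        checks = reproduce_printed_tables()
        assert {c.name for c in checks} >= {
            "sensitivity_pct", "specificity_pct", "youden", "prevalence_pct",
            "favorable_in_good_pct", "favorable_in_poor_pct",
            "good_in_laa_pct", "good_in_ce_pct", "grade3_boundary_deg",
        }
        assert all(c.ok for c in checks)

    def test_fixture_schema_mismatch_rejected(self):
        with pytest.raises(ValueError, match="schema"):
            reproduce_printed_tables(fixtures={"bogus": 1})

    def test_round_half_up_behaviour(self):
        assert round_half_up(12.5, 0) == 13.0
        assert round_half_up(34.259, 1) == 34.3
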