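"""Decision tree, M1 median split and evaluation statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from brcastrat import (
    LM22_CELL_TYPES,
    ResponseTreeClassifier,
    cibersort_group_comparison,
    cox_ph,
    deconvolve_scores,
    evaluate_predictions,
    fisher_exact_2x2,
    logistic_association,
    m1_median_split,
    predict_response,
)
from brcastrat.predictor import table_to_binary


class TestM1Split:
    def test_median_over_nonbrca_subset_only(self):
        scores = pd.Series([0.1, 0.3, 0.5, 0.4, 9.0], index=list("abcde"))
        states = pd.Series(["nonBRCA", "nonBRCA", "nonBRCA", "BRCAmut", "BRCAmut"], index=list("abcde"))
        labels, median = m1_median_split(scores, states)
        assert median == pytest.approx(0.3)
        assert labels["d"] == "high"  # 0.4 > 0.3 despite being BRCAmut

    def test_score_at_median_is_low(self):
        scores = pd.Series([0.1, 0.3, 0.5], index=list("abc"))
        states = pd.Series(["nonBRCA"] * 3, index=list("abc"))
        labels, _ = m1_median_split(scores, states)
        assert labels["b"] == "low"

    def test_even_n_midpoint_convention(self):
        scores = pd.Series([0.1, 0.2, 0.3, 0.4], index=list("abcd"))
        states = pd.Series(["nonBRCA"] * 4, index=list("abcd"))
        _, median = m1_median_split(scores, states)
        assert median == pytest.approx(0.25)

    def test_no_nonbrca_samples_is_error(self):
        with pytest.raises(ValueError):
            m1_median_split(pd.Series([0.1]), pd.Series(["BRCAmut"]))


class TestDecisionTree:
    @pytest.mark.parametrize(
        "state, m1, predicted, branch",
        [
            ("BRCAmut", "high", "responder", "brca_mut"),
            ("BRCAmut", None, "responder", "brca_mut"),
            ("BRCA1meth", "high", "non-responder", "brca1_meth"),
            ("nonBRCA", "high", "responder", "nonbrca_m1_high"),
            ("nonBRCA", "low", "non-responder", "nonbrca_m1_low"),
            ("nonBRCA", None, "unpredictable", "nonbrca_m1_missing"),
        ],
    )
    def test_tree_is_total_with_one_unpredictable_cell(self, state, m1, predicted, branch):
        p = predict_response(state, m1)
        assert (p.predicted, p.branch) == (predicted, branch)

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError):
            predict_response("BRCA3", "high")

    def test_estimator_fit_learns_nonbrca_median(self):
        X = pd.DataFrame(
            {
                "sample_id": list("abcdef"),
                "state": ["nonBRCA"] * 4 + ["BRCAmut", "BRCA1meth"],
                "m1_score": [0.1, 0.2, 0.3, 0.4, 0.9, 0.9],
            }
        )
        clf = ResponseTreeClassifier().fit(X)
        assert clf.m1_median_ == pytest.approx(0.25)
        preds = clf.predict(X)
        assert list(preds) == [
            "non-responder", "non-responder", "responder", "responder",
            "responder", "non-responder",
        ]


class TestEvaluation:
    def test_printed_subgroup_fractions(self):
        preds = pd.Series(
            ["responder"] * 19 + ["non-responder"] * 11,
            index=[f"s{i}" for i in range(30)],
        )
        outcomes = pd.Series(
            [True] * 16 + [False] * 3 + [True] * 1 + [False] * 10,
            index=[f"s{i}" for i in range(30)],
        )
        m = evaluate_predictions(preds, outcomes)
        assert m["responder_outcome_pct"] == pytest.approx(84.2, abs=0.05)
        assert m["nonresponder_outcome_pct"] == pytest.approx(9.1, abs=0.05)
        assert m["accuracy_pct"] == pytest.approx(100 * 26 / 30, abs=0.05)

    def test_perfect_predictions(self):
        preds = pd.Series(["responder", "non-responder"], index=["a", "b"])
        outcomes = pd.Series([True, False], index=["a", "b"])
        assert evaluate_predictions(preds, outcomes)["accuracy_pct"] == 100.0

    def test_unpredictable_samples_excluded(self):
        preds = pd.Series(["responder", "unpredictable"], index=["a", "b"])
        outcomes = pd.Series([True, True], index=["a", "b"])
        assert evaluate_predictions(preds, outcomes)["n"] == 1

    def test_no_overlap_is_error(self):
        with pytest.raises(ValueError):
            evaluate_predictions(pd.Series(dtype=object), pd.Series(dtype=bool))


def fisher_two_sided_oracle(table):
    """Independent hypergeometric enumeration of the two-sided exact p."""
    a, b = table[0]
    c, d = table[1]
    n = a + b + c + d
    row1, col1 = a + b, a + c
    p_obs = hypergeom.pmf(a, n, col1, row1)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = hypergeom.pmf(k, n, col1, row1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(1.0, total)


class TestFisher:
    @pytest.mark.parametrize(
        "table, printed",
        [([[10, 1], [5, 11]], 0.005), ([[8, 1], [2, 6]], 0.015)],
    )
    def test_printed_worked_examples(self, table, printed):
        assert round(fisher_exact_2x2(table).p_value, 3) == printed

    def test_null_table(self):
        r = fisher_exact_2x2([[5, 5], [5, 5]])
        assert r.p_value == pytest.approx(1.0)
        assert r.estimate == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [2, 3]])

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    def test_matches_hypergeometric_enumeration(self, a, b, c, d):
        if a + b + c + d == 0 or a + b + c + d > 40:
            return
        table = [[a, b], [c, d]]
        assert fisher_exact_2x2(table).p_value == pytest.approx(
            fisher_two_sided_oracle(table), abs=1e-9
        )


class TestLogistic:
    def test_printed_tdp_brca1_association(self):
        y, x = table_to_binary([[16, 1], [2, 23]])
        r = logistic_association(y, x)
        assert r.p_value == pytest.approx(3.9e-5, rel=0.05)
        assert r.estimate == pytest.approx(184.0, rel=0.01)

    def test_null_predictor(self, rng):
        y = rng.integers(0, 2, 2000)
        x = rng.normal(0, 1, 2000)
        r = logistic_association(y, x)
        assert r.estimate == pytest.approx(1.0, abs=0.2)
        assert r.p_value > 0.001

    def test_complete_separation_flagged(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([1, 1, 1, 0, 0, 0])
        r = logistic_association(y, x)
        assert r.p_value is None

    def test_single_outcome_level_rejected(self):
        with pytest.raises(ValueError):
            logistic_association([1, 1, 1], [0, 1, 0])


class TestCox:
    def test_identical_arms_hr_near_one(self, rng):
        t = rng.exponential(100, 400)
        e = np.ones(400, dtype=bool)
        x = np.repeat([0, 1], 200)
        r = cox_ph(t, e, x)
        assert r.estimate == pytest.approx(1.0, abs=0.35)

    def test_simulated_hr_recovered(self, rng):
        n = 500
        t0 = rng.exponential(100, n)
        t1 = rng.exponential(200, n)  # hazard halved -> HR 0.5
        t = np.concatenate([t0, t1])
        e = np.ones(2 * n, dtype=bool)
        x = np.repeat([0, 1], n)
        r = cox_ph(t, e, x)
        assert 0.4 < r.estimate < 0.62
        assert r.ci_low < r.estimate < r.ci_high

    def test_continuous_covariate_recovery(self, rng):
        # log-hazard -0.2 per unit of a continuous score
        n = 800
        x = rng.normal(0, 1, n)
        t = rng.exponential(1.0 / (0.01 * np.exp(-0.2 * x)))
        r = cox_ph(t, np.ones(n, dtype=bool), x)
        se = (np.log(r.ci_high) - np.log(r.ci_low)) / (2 * 1.96)
        assert abs(np.log(r.estimate) - (-0.2)) < 2 * se

    def test_no_events_is_error(self):
        with pytest.raises(ValueError):
            cox_ph([1, 2], [False, False], [0, 1])


class TestImmuneComparison:
    def _profiles(self, rng, n=30, shift_type=None, shift=0.0):
        data = rng.normal(0.05, 0.02, (2 * n, len(LM22_CELL_TYPES)))
        df = pd.DataFrame(data, columns=list(LM22_CELL_TYPES),
                          index=[f"s{i}" for i in range(2 * n)])
        grouping = pd.Series([True] * n + [False] * n, index=df.index)
        if shift_type:
            df.loc[grouping, shift_type] += shift
        return df, grouping

    def test_identical_distributions_all_nonsignificant(self, rng):
        df, grouping = self._profiles(rng)
        res = cibersort_group_comparison(df, grouping)
        assert len(res) == 22
        assert (res["p_adjusted"] > 0.05).all()

    def test_shifted_cell_type_detected_after_bonferroni(self, rng):
        df, grouping = self._profiles(rng, shift_type="Macrophages M1", shift=0.06)  # 3 SD
        res = cibersort_group_comparison(df, grouping).set_index("cell_type")
        assert res.loc["Macrophages M1", "p_adjusted"] < 0.05

    def test_bonferroni_multiplies_and_caps(self, rng):
        df, grouping = self._profiles(rng)
        res = cibersort_group_comparison(df, grouping)
        expected = np.minimum(1.0, res["p_value"] * 22)
        np.testing.assert_allclose(res["p_adjusted"], expected)


class TestDeconvolution:
    def _signature(self, rng):
        genes = [f"g{i}" for i in range(100)]
        return pd.DataFrame(
            rng.uniform(0, 10, (100, 3)), index=genes, columns=["M1", "M2", "CD8"]
        )

    def test_pure_profile_recovered(self, rng):
        sig = self._signature(rng)
        fractions, resid = deconvolve_scores(sig["M1"], sig)
        assert fractions["M1"] == pytest.approx(1.0, abs=1e-6)
        assert resid < 1e-9

    def test_mixture_recovered(self, rng):
        sig = self._signature(rng)
        profile = 0.6 * sig["M1"] + 0.4 * sig["M2"]
        fractions, _ = deconvolve_scores(profile, sig)
        assert fractions["M1"] == pytest.approx(0.6, abs=0.05)
        assert fractions["M2"] == pytest.approx(0.4, abs=0.05)

    def test_no_gene_overlap_is_error(self, rng):
        sig = self._signature(rng)
        profile = pd.Series([1.0], index=["other_gene"])
        with pytest.raises(ValueError):
            deconvolve_scores(profile, sig)
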