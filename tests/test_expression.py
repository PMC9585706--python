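"""Expression normalisation, qPCR ΔΔCt, DEG selection, enrichment, correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brcastrat.expression import (
    QpcrMeasurement,
    ddct_relative_expression,
    immune_gene_enrichment,
    methylation_expression_correlation,
    percentile_rank_transform,
    select_degs,
    two_group_deg_stats,
    upper_quartile_normalize,
)


class TestUpperQuartile:
    def test_identical_samples_unchanged_up_to_scale(self):
        m = pd.DataFrame({"s1": [1.0, 2, 3, 4], "s2": [1.0, 2, 3, 4]})
        out = upper_quartile_normalize(m)
        pd.testing.assert_frame_equal(out / out.iloc[0, 0], m / m.iloc[0, 0])

    def test_scaled_sample_equalised(self):
        m = pd.DataFrame({"s1": [1.0, 2, 3, 4], "s2": [2.0, 4, 6, 8]})
        out = upper_quartile_normalize(m)
        np.testing.assert_allclose(out["s1"], out["s2"])

    def test_linear_interpolation_percentile(self):
        # UQ of nonzero (1,2,3,4) = 3.25; single sample -> cohort factor = 3.25
        m = pd.DataFrame({"s1": [1.0, 2, 3, 4]})
        out = upper_quartile_normalize(m)
        np.testing.assert_allclose(out["s1"], np.array([1, 2, 3, 4]) / 3.25 * 3.25)

    def test_zeros_excluded_from_quantile(self):
        m = pd.DataFrame({"s1": [0.0, 0, 1, 2, 3, 4]})
        out = upper_quartile_normalize(m)
        # quantile over nonzero (1,2,3,4) = 3.25, not over all six values
        assert out["s1"].iloc[-1] == pytest.approx(4 / 3.25 * 3.25)

    def test_all_zero_sample_is_error(self):
        with pytest.raises(ValueError):
            upper_quartile_normalize(pd.DataFrame({"s1": [0.0, 0.0]}))


class TestPercentileRank:
    def test_strictly_increasing_ranks(self):
        m = pd.DataFrame({"s1": [1.0, 5.0, 9.0]})
        np.testing.assert_allclose(
            percentile_rank_transform(m)["s1"], [1 / 3, 2 / 3, 1.0]
        )

    def test_ties_get_mean_rank(self):
        m = pd.DataFrame({"s1": [2.0, 2.0, 5.0]})
        np.testing.assert_allclose(percentile_rank_transform(m)["s1"], [0.5, 0.5, 1.0])

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(min_value=0.1, max_value=1e4), min_size=3, max_size=30, unique=True))
    def test_invariant_under_monotone_transform(self, values):
        m = pd.DataFrame({"s1": values})
        a = percentile_rank_transform(m)
        b = percentile_rank_transform(np.log(m + 1) * 3.7)
        pd.testing.assert_frame_equal(a, b)


class TestDdct:
    def _meas(self, target, housekeeping, sid="s"):
        return QpcrMeasurement(sid, tuple(target), tuple(housekeeping))

    def test_identical_to_calibrator_is_unity(self):
        m = self._meas([25, 25.2, 24.8], [20, 20.1, 19.9])
        assert ddct_relative_expression(m, m) == pytest.approx(1.0)

    @pytest.mark.parametrize("ddct, rq", [(3, 0.125), (-1, 2.0), (0, 1.0)])
    def test_closed_form(self, ddct, rq):
        cal = self._meas([25.0], [20.0])
        sample = self._meas([25.0 + ddct], [20.0])
        assert ddct_relative_expression(sample, cal) == pytest.approx(rq)

    def test_shifting_target_ct_by_one_halves_rq(self):
        cal = self._meas([25.0], [20.0])
        a = ddct_relative_expression(self._meas([26.0, 25.5], [20.0]), cal)
        b = ddct_relative_expression(self._meas([27.0, 26.5], [20.0]), cal)
        assert b == pytest.approx(a / 2)

    def test_missing_replicates_rejected(self):
        with pytest.raises(ValueError):
            QpcrMeasurement("s", (), (20.0,))


class TestDegSelection:
    @pytest.mark.parametrize(
        "p, lfc, direction",
        [
            (0.01, 1.5, "up"), (0.01, -1.5, "down"),
            (0.01, 1.0, "none"),  # strict > on |lfc|
            (0.06, 3.0, "none"), (0.05, 3.0, "none"),  # strict < on p
        ],
    )
    def test_threshold_rules(self, p, lfc, direction):
        table = pd.DataFrame({"gene": ["g"], "log2_fold_change": [lfc], "p_value": [p]})
        assert select_degs(table)["direction"].iloc[0] == direction

    def test_threshold_monotonicity(self, rng):
        table = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(200)],
                "log2_fold_change": rng.normal(0, 2, 200),
                "p_value": rng.uniform(0, 1, 200),
            }
        )
        strict = set(select_degs(table).query("direction != 'none'")["gene"])
        relaxed = set(
            select_degs(table, p_threshold=0.2, lfc_threshold=0.5).query("direction != 'none'")["gene"]
        )
        assert strict <= relaxed

    def test_two_group_stats_detect_shift(self, rng):
        m = pd.DataFrame(
            rng.normal(0, 1, (50, 20)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{i}" for i in range(20)],
        ).abs()
        m.iloc[0, :10] += 10  # strong shift in group A
        stats = two_group_deg_stats(m, [f"s{i}" for i in range(10)], [f"s{i}" for i in range(10, 20)])
        assert stats.iloc[0]["p_value"] < 0.01


class TestEnrichment:
    def test_null_odds_ratio_near_one(self):
        universe = {f"g{i}" for i in range(1000)}
        immune = {f"g{i}" for i in range(200)}  # 20% of universe
        deg = {f"g{i}" for i in range(0, 1000, 5)}  # also 20% immune
        odds, p, _ = immune_gene_enrichment(deg, immune, universe)
        assert odds == pytest.approx(1.0, abs=0.2)

    def test_cross_product_oracle(self):
        # constructed table [[30,10],[70,390]] -> OR 16.71
        universe = {f"g{i}" for i in range(500)}
        deg = {f"g{i}" for i in range(40)}
        immune = {f"g{i}" for i in range(30)} | {f"g{i}" for i in range(40, 110)}
        odds, p, table = immune_gene_enrichment(deg, immune, universe)
        assert table.tolist() == [[30, 10], [70, 390]]
        assert odds == pytest.approx((30 * 390) / (10 * 70), rel=1e-9)

    def test_empty_deg_set_reported_na(self):
        odds, p, _ = immune_gene_enrichment(set(), {"g1"}, {"g1", "g2"})
        assert np.isnan(odds) and p == 1.0

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError):
            immune_gene_enrichment({"g1"}, {"g1"}, set())


class TestMethylationCorrelation:
    def test_perfect_negative_correlation(self):
        r, _ = methylation_expression_correlation([10, 50, 90], [9, 5, 1])
        assert r == pytest.approx(-1.0)

    def test_independent_pairs_near_zero(self, rng):
        r, _ = methylation_expression_correlation(
            rng.uniform(0, 100, 1000), rng.normal(0, 1, 1000)
        )
        assert abs(r) < 0.1

    def test_generator_round_trip(self):
        # cohort generated with target r = -0.82 recovers it within 0.1 at n=200
        from brcastrat import CohortConfig, generate_cohort

        cfg = CohortConfig(
            n_per_group={"BRCAmut": 0, "BRCA1meth": 200, "nonBRCA": 0}, seed=3
        )
        tables = generate_cohort(cfg)
        m = tables.meth_expression
        r, _ = methylation_expression_correlation(
            m["meth_percent"], m["brca1_log2_expression"]
        )
        assert r == pytest.approx(-0.82, abs=0.1)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError):
            methylation_expression_correlation([50, 50, 50], [1, 2, 3])
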