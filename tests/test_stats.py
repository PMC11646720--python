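"""Contingency-table and t-test statistics against published values and oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emprs import stats
from emprs.errors import (
    DegenerateTableError,
    InvalidConfigError,
    InvalidInputError,
    ResourceLimitError,
)

from _oracles import fisher_2x2_oracle, rxc_exact_oracle


class TestPearsonChi2:
    @pytest.mark.parametrize(
        "table, expected_chi2",
        [
            ([[36, 63], [135, 892]], 37.79),   # high-risk proportion, EM vs PGT-M controls
            ([[36, 63], [37, 331]], 40.94),    # EM vs normal-menopause controls
            ([[27, 29], [6, 31]], 9.96),       # husband smokes
            ([[29, 28], [4, 31]], 14.67),      # husband drinks heavily
            ([[9, 5], [27, 58]], 5.49),        # COVID-19 vaccination
            ([[25, 55], [11, 8]], 4.71),       # family history of EM
            ([[13, 11], [23, 52]], 4.34),      # staying up late
        ],
    )
    def test_published_tables(self, table, expected_chi2):
        res = stats.pearson_chi2(table)
        assert res.test_name == "pearson_chi2"
        assert res.statistic == pytest.approx(expected_chi2, abs=0.005)
        assert res.df == 1

    def test_homogeneous_table_gives_zero(self):
        res = stats.pearson_chi2([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_raises(self):
        with pytest.raises(DegenerateTableError):
            stats.pearson_chi2([[0, 0], [5, 7]])

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=60, derandomize=True)
    def test_invariant_under_row_and_column_swap(self, a, b, c, d):
        table = np.array([[a + 1, b], [c, d + 1]])  # +1 guards zero margins
        base = stats.pearson_chi2(table).statistic
        assert stats.pearson_chi2(table[::-1]).statistic == pytest.approx(base)
        assert stats.pearson_chi2(table[:, ::-1]).statistic == pytest.approx(base)
        assert stats.pearson_chi2(table.T).statistic == pytest.approx(base)


class TestFisherExact:
    def test_balanced_table_is_one(self):
        assert stats.fisher_exact_2x2([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_perfect_separation(self):
        # two attainable extreme tables out of C(10,5)=252
        assert stats.fisher_exact_2x2([[5, 0], [0, 5]]).p_value == pytest.approx(2 / 252)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(0, 15, size=4)
        p = stats.fisher_exact_2x2([[a, b], [c, d]]).p_value
        assert p == pytest.approx(fisher_2x2_oracle(int(a), int(b), int(c), int(d)), abs=1e-10)


class TestFreemanHalton:
    def test_family_satisfaction_table(self):
        # 2×4 ordinal table: exact p matches the published group comparison
        res = stats.freeman_halton([[0, 6, 27, 3], [4, 6, 35, 18]])
        assert res.p_value == pytest.approx(0.024, abs=5e-4)
        assert res.statistic is None

    @pytest.mark.parametrize("seed", range(8))
    def test_reduces_to_fisher_on_2x2(self, seed):
        rng = np.random.default_rng(100 + seed)
        table = rng.integers(0, 12, size=(2, 2))
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            table = table + 1
        p_fh = stats.freeman_halton(table).p_value
        p_fisher = stats.fisher_exact_2x2(table).p_value
        assert p_fh == pytest.approx(p_fisher, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_rxc_enumeration_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        shape = [(2, 3), (3, 3), (2, 4)][seed % 3]
        table = rng.integers(0, 6, size=shape)
        table[0, 0] += 1  # avoid fully empty tables
        p = stats.freeman_halton(table).p_value
        assert p == pytest.approx(rxc_exact_oracle(table), abs=1e-10)

    def test_table_probabilities_sum_to_one(self):
        # total mass over all tables with the observed margins
        from emprs.stats import _enumerate_tables, _log_table_prob

        table = np.array([[3, 5, 2], [4, 1, 6]])
        row, col = table.sum(axis=1), table.sum(axis=0)
        total = sum(
            np.exp(_log_table_prob(t, row, col, table.sum()))
            for t in _enumerate_tables(row, col)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_guard_limit_advises_monte_carlo(self):
        big = np.full((4, 4), 60)
        with pytest.raises(ResourceLimitError):
            stats.freeman_halton(big)

    def test_monte_carlo_mode_close_to_exact(self):
        table = [[0, 6, 27, 3], [4, 6, 35, 18]]
        exact = stats.freeman_halton(table).p_value
        mc = stats.freeman_halton(table, method="monte-carlo", seed=1, n_monte_carlo=20000)
        assert mc.p_value == pytest.approx(exact, abs=0.01)
        with pytest.raises(InvalidConfigError):
            stats.freeman_halton(table, method="monte-carlo")


class TestOddsRatioWoolf:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[36, 63], [135, 892]], (3.78, 2.41, 5.91)),
            ([[36, 63], [37, 331]], (5.11, 3.00, 8.70)),
        ],
    )
    def test_published_odds_ratios(self, table, expected):
        orr = stats.odds_ratio_woolf(table)
        assert orr.odds_ratio == pytest.approx(expected[0], abs=0.005)
        assert orr.ci_low == pytest.approx(expected[1], abs=0.005)
        assert orr.ci_high == pytest.approx(expected[2], abs=0.005)
        assert not orr.continuity_corrected

    def test_balanced_table_symmetric_about_one(self):
        orr = stats.odds_ratio_woolf([[7, 7], [7, 7]])
        assert orr.odds_ratio == pytest.approx(1.0)
        assert orr.ci_low * orr.ci_high == pytest.approx(1.0)  # symmetric on log scale

    def test_zero_cell_haldane_anscombe(self):
        orr = stats.odds_ratio_woolf([[0, 10], [5, 5]])
        assert orr.continuity_corrected
        assert orr.odds_ratio == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))

    def test_zero_line_raises(self):
        with pytest.raises(DegenerateTableError):
            stats.odds_ratio_woolf([[0, 0], [5, 5]])

    @given(st.integers(1, 40), st.integers(1, 40), st.integers(1, 40), st.integers(1, 40))
    @settings(max_examples=60, derandomize=True)
    def test_row_swap_inverts(self, a, b, c, d):
        orr = stats.odds_ratio_woolf([[a, b], [c, d]])
        swapped = stats.odds_ratio_woolf([[c, d], [a, b]])
        assert swapped.odds_ratio == pytest.approx(1 / orr.odds_ratio)
        assert swapped.ci_low == pytest.approx(1 / orr.ci_high)


class TestStudentT:
    def test_published_height_comparison(self):
        # the recomputed t from rounded summaries is −1.9972 vs printed −1.99
        res = stats.student_t(160.64, 4.57, 36, 162.90, 5.84, 63)
        assert res.statistic == pytest.approx(-1.99, abs=0.01)
        assert res.p_value == pytest.approx(0.049, abs=5e-4)
        assert res.df == 97

    def test_identical_groups(self):
        res = stats.student_t(10.0, 2.0, 20, 10.0, 2.0, 25)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_summary_equals_raw_overload(self):
        rng = np.random.default_rng(0)
        x1, x2 = rng.normal(0, 1, 30), rng.normal(0.4, 1.3, 45)
        raw = stats.student_t_from_samples(x1, x2)
        summ = stats.student_t(
            x1.mean(), x1.std(ddof=1), 30, x2.mean(), x2.std(ddof=1), 45
        )
        assert raw.statistic == pytest.approx(summ.statistic)
        assert raw.p_value == pytest.approx(summ.p_value)

    def test_small_groups_raise(self):
        with pytest.raises(InvalidInputError):
            stats.student_t(1.0, 1.0, 1, 2.0, 1.0, 10)

    def test_welch_differs_under_variance_imbalance(self):
        pooled = stats.student_t(0, 1.0, 10, 1, 5.0, 50)
        welch = stats.student_t(0, 1.0, 10, 1, 5.0, 50, welch=True)
        assert pooled.statistic != pytest.approx(welch.statistic)


class TestCompareGroups:
    def test_auto_selects_exact_for_sparse_ordinal(self):
        df = pd.concat(
            [
                pd.DataFrame({"group": "high", "satisfaction": ["d"] * 0 + ["a"] * 6 + ["r"] * 27 + ["v"] * 3}),
                pd.DataFrame({"group": "intermediate", "satisfaction": ["d"] * 4 + ["a"] * 6 + ["r"] * 35 + ["v"] * 18}),
            ],
            ignore_index=True,
        )
        report = stats.compare_groups(df, "group", {"satisfaction": "categorical"})
        first = report[report["test"] != ""].iloc[0]
        assert first["test"] == "freeman_halton"
        assert first["p_value"] == pytest.approx(0.024, abs=5e-4)

    def test_chi2_selected_when_expected_counts_large(self):
        df = pd.concat(
            [
                pd.DataFrame({"group": "high", "smokes": [1] * 6 + [0] * 27}),
                pd.DataFrame({"group": "intermediate", "smokes": [1] * 31 + [0] * 29}),
            ],
            ignore_index=True,
        )
        report = stats.compare_groups(df, "group", {"smokes": "categorical"})
        first = report[report["test"] != ""].iloc[0]
        assert first["test"] == "pearson_chi2"
        assert first["statistic"] == pytest.approx(9.96, abs=0.005)

    def test_pairwise_dropping_of_non_applicable(self):
        df = pd.DataFrame(
            {
                "group": ["high"] * 4 + ["intermediate"] * 4,
                "x": [1.0, 2.0, np.nan, 3.0, 2.0, 4.0, 5.0, np.nan],
            }
        )
        report = stats.compare_groups(df, "group", {"x": "continuous"})
        assert report.iloc[0]["n"] == 6  # the two NaN rows dropped for this variable only

    def test_single_level_variable_skipped(self):
        df = pd.DataFrame({"group": ["high", "intermediate"] * 5, "c": ["yes"] * 10})
        report = stats.compare_groups(df, "group", {"c": "categorical"})
        assert "skipped" in report.iloc[0]["note"]

    def test_markdown_report_uses_table_dialect(self):
        df = pd.concat(
            [
                pd.DataFrame({"group": "high", "h": np.random.default_rng(1).normal(160, 5, 36)}),
                pd.DataFrame({"group": "intermediate", "h": np.random.default_rng(2).normal(163, 6, 63)}),
            ],
            ignore_index=True,
        )
        report = stats.compare_groups(df, "group", {"h": "continuous"})
        md = stats.format_report_markdown(report)
        assert "t=" in md and "|" in md
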