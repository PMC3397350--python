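"""Reporting statistics against independent reference computations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import biofortsim as bf
from biofortsim.report import (
    covariates_from_cohort,
    render_quartile_markdown,
    render_scenario_markdown,
)

from conftest import make_subject


class TestPairedT:
    def test_identical_vectors(self):
        res = bf.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == 0.0 and res["p"] == 1.0 and res["df"] == 2

    def test_textbook_differences(self):
        # differences (1, 2, 3): t = mean/ (sd/sqrt(3)) = 2 / (1/sqrt(3))
        res = bf.paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert round(res["t"], 3) == 3.464
        assert res["df"] == 2

    def test_matches_hand_formula_on_random_pairs(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            n = int(rng.integers(3, 40))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            res = bf.paired_t(x, y)
            d = x - y
            t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            p_hand = 2 * stats.t.sf(abs(t_hand), n - 1)
            assert res["t"] == pytest.approx(t_hand, abs=1e-8)
            assert res["p"] == pytest.approx(p_hand, abs=1e-8)

    def test_constant_nonzero_difference_is_error(self):
        with pytest.raises(bf.ValidationError):
            bf.paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])


class TestChiSquare:
    def test_homogeneous_table(self):
        res = bf.chisq_2xk([[10, 10], [10, 10]])
        assert res["statistic"] == 0.0 and res["p"] == 1.0

    def test_hand_computed_2x2(self):
        res = bf.chisq_2xk([[20, 10], [10, 20]])
        assert round(res["statistic"], 3) == 6.667
        assert res["df"] == 1

    def test_matches_hand_pearson_on_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            k = int(rng.integers(2, 6))
            table = rng.integers(5, 50, size=(2, k)).astype(float)
            res = bf.chisq_2xk(table)
            row = table.sum(axis=1, keepdims=True)
            col = table.sum(axis=0, keepdims=True)
            expected = row @ col / table.sum()
            stat_hand = ((table - expected) ** 2 / expected).sum()
            assert res["statistic"] == pytest.approx(stat_hand, abs=1e-8)
            assert res["df"] == k - 1
            assert res["p"] == pytest.approx(
                stats.chi2.sf(stat_hand, k - 1), abs=1e-8
            )

    def test_zero_expected_cell_is_error(self):
        with pytest.raises(bf.ValidationError):
            bf.chisq_2xk([[0, 10], [0, 20]])


class TestCochranArmitage:
    def test_flat_proportions_give_no_trend(self):
        res = bf.cochran_armitage_trend([5, 5, 5, 5], [50, 50, 50, 50])
        assert res["z"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_matches_linear_by_linear_identity(self):
        """CA z^2 equals N/(N-1) times the squared linear-by-linear z-score
        (the two tests differ only in their variance denominator)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        for _ in range(5):
            totals = rng.integers(30, 80, size=4)
            cases = np.array([int(rng.integers(1, t - 1)) for t in totals])
            res = bf.cochran_armitage_trend(cases, totals)
            table = np.vstack([cases, totals - cases])  # 2 x 4
            lbl = sm.stats.Table(table).test_ordinal_association()
            n = totals.sum()
            assert res["z"] ** 2 == pytest.approx(
                float(lbl.zscore) ** 2 * n / (n - 1), rel=1e-8
            )

    def test_degenerate_all_negative_is_error(self):
        with pytest.raises(bf.ValidationError):
            bf.cochran_armitage_trend([0, 0], [10, 10])


class TestTrendRegression:
    def test_perfectly_linear_outcome(self):
        q = np.tile([1, 2, 3, 4], 10)
        y = 2.5 * q + 1.0
        res = bf.trend_regression(y, q)
        assert res["slope"] == pytest.approx(2.5, abs=1e-10)
        assert res["p"] < 1e-12

    def test_matches_normal_equations_with_covariates(self):
        rng = np.random.default_rng(6)
        n = 120
        q = rng.integers(1, 5, size=n)
        covs = pd.DataFrame(
            {
                "age": rng.integers(20, 80, size=n).astype(float),
                "sex": rng.choice(["male", "female"], size=n),
                "energy": rng.normal(2300, 400, size=n),
            }
        )
        y = 0.8 * q + 0.01 * covs["age"].to_numpy() + rng.normal(size=n)
        res = bf.trend_regression(y, q, covs)
        # independent solve of the normal equations
        X = np.column_stack(
            [
                np.ones(n),
                q.astype(float),
                covs["age"],
                (covs["sex"] == "female").astype(float),
                covs["energy"],
            ]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res["slope"] == pytest.approx(beta[1], abs=1e-10)

    def test_null_p_values_are_uniform(self):
        """Type-I error: with no true trend, p is Uniform(0, 1)."""
        rng = np.random.default_rng(2024)
        pvals = []
        q = np.tile([1, 2, 3, 4], 15)
        for _ in range(500):
            y = rng.normal(size=q.size)
            pvals.append(bf.trend_regression(y, q)["p"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_aliased_design_is_error(self):
        q = np.tile([1, 2, 3, 4], 5)
        covs = pd.DataFrame({"shadow": q.astype(float)})  # duplicates quartile
        with pytest.raises(bf.ValidationError, match="aliased"):
            bf.trend_regression(np.arange(20.0), q, covs)

    def test_bad_quartile_index_rejected(self):
        with pytest.raises(bf.ValidationError):
            bf.trend_regression([1.0, 2.0], [1, 5])


class TestScenarioSummary:
    def _hand_cohort(self):
        return [
            make_subject(sid="a", sex="male", age=30, rice_g_day=300.0,
                         zinc_rice=5.1, zinc_total=9.0, energy=2500.0),
            make_subject(sid="b", sex="male", age=55, rice_g_day=100.0,
                         zinc_rice=1.7, zinc_total=7.0, energy=1900.0),
            make_subject(sid="c", sex="female", age=40, rice_g_day=200.0,
                         zinc_rice=3.4, zinc_total=12.0, energy=2200.0),
            make_subject(sid="d", sex="female", age=65, rice_g_day=0.0,
                         zinc_rice=0.0, zinc_total=6.0, energy=1700.0),
            make_subject(sid="e", sex="female", age=25, rice_g_day=400.0,
                         zinc_rice=6.8, zinc_total=15.0, energy=2800.0),
        ]

    def test_hand_cohort_cells(self, dri):
        cohort = self._hand_cohort()
        scenarios = [bf.Scenario("normal", 1.7), bf.Scenario("mid", 2.7)]
        summary = bf.scenario_summary(cohort, scenarios, dri)
        t = summary.table
        # baseline: hand-computed cells
        rice = np.array([5.1, 1.7, 3.4, 0.0, 6.8])
        total = np.array([9.0, 7.0, 12.0, 6.0, 15.0])
        assert t.loc["zinc_from_rice_mean_mg_day", "normal"] == pytest.approx(
            rice.mean(), abs=1e-10
        )
        assert t.loc["zinc_from_rice_sd_mg_day", "normal"] == pytest.approx(
            rice.std(ddof=1), abs=1e-10
        )
        shares = 100 * rice / total
        assert t.loc["rice_share_mean_of_shares_pct", "normal"] == pytest.approx(
            shares.mean(), abs=1e-10
        )
        assert t.loc["rice_share_ratio_of_means_pct", "normal"] == pytest.approx(
            100 * rice.mean() / total.mean(), abs=1e-10
        )
        # insufficiency by hand: a (9<10), b (7<7.667), d (6<7.667) -> 3/5
        assert t.loc["insufficiency_pct", "normal"] == pytest.approx(60.0)
        # absorbed by hand
        absorbed = np.array(
            [0.26 * 9.0, 0.26 * 7.0, 0.34 * 12.0, 0.34 * 6.0, 0.34 * 15.0]
        )
        assert t.loc["absorbed_zinc_mean_mg_day", "normal"] == pytest.approx(
            absorbed.mean(), abs=1e-10
        )
        # absorbed inadequacy: males 2.34 and 1.82 < 2.69; female d 2.04 > 1.86
        assert t.loc["absorbed_inadequacy_pct", "normal"] == pytest.approx(40.0)
        # intermediate scenario: rice scaled by 2.7/1.7
        ratio = 2.7 / 1.7
        assert t.loc["zinc_from_rice_mean_mg_day", "mid"] == pytest.approx(
            ratio * rice.mean(), abs=1e-10
        )
        total_mid = total + rice * (ratio - 1)
        # b: 8.0 > 7.667 recovers; a: 12.0 >= 10 recovers; d unchanged -> 1/5
        assert t.loc["insufficiency_pct", "mid"] == pytest.approx(20.0)
        assert t.loc["zinc_total_mean_mg_day", "mid"] == pytest.approx(
            total_mid.mean(), abs=1e-10
        )

    def test_identical_scenario_comparison_is_null(self, dri):
        cohort = self._hand_cohort()
        scenarios = [bf.Scenario("normal", 1.7), bf.Scenario("copy", 1.7)]
        summary = bf.scenario_summary(cohort, scenarios, dri)
        assert summary.comparisons.loc["copy", "t_vs_baseline"] == 0.0
        assert summary.comparisons.loc["copy", "t_p"] == 1.0
        assert summary.comparisons.loc["copy", "insufficiency_chi2"] == pytest.approx(0.0)

    def test_empty_cohort_rejected(self, dri):
        with pytest.raises(bf.ValidationError):
            bf.scenario_summary([], [bf.Scenario("normal", 1.7)], dri)

    def test_monotone_rows_on_synthetic_cohort(self, default_cohort, dri):
        summary = bf.scenario_summary(
            default_cohort.subjects, list(bf.DEFAULT_SCENARIOS), dri
        )
        t = summary.table
        rice_means = t.loc["zinc_from_rice_mean_mg_day"]
        absorbed = t.loc["absorbed_zinc_mean_mg_day"]
        insuf = t.loc["insufficiency_pct"]
        assert rice_means.is_monotonic_increasing and rice_means.nunique() == 3
        assert absorbed.is_monotonic_increasing and absorbed.nunique() == 3
        assert (insuf.diff().dropna() <= 0).all()
        assert (summary.comparisons["t_p"] < 0.001).all()

    def test_markdown_rendering_runs(self, dri):
        cohort = self._hand_cohort()
        summary = bf.scenario_summary(
            cohort, [bf.Scenario("normal", 1.7), bf.Scenario("mid", 2.7)], dri
        )
        text = render_scenario_markdown(summary)
        assert "Zinc intake from rice" in text
        assert "household" in text


class TestQuartileReport:
    def test_structure_and_bounds(self, default_cohort, dri, loadings):
        report = bf.quartile_report(
            default_cohort.subjects,
            loadings,
            list(bf.DEFAULT_SCENARIOS),
            dri,
            "traditional",
        )
        assert list(report.table.index) == ["Q1", "Q2", "Q3", "Q4"]
        sizes = report.table["n"]
        assert sizes.max() - sizes.min() <= 1 and sizes.sum() == 2819
        for col in report.table.columns:
            if col.startswith("insufficiency_pct"):
                assert report.table[col].between(0, 100).all()
        # traditional pattern: rice intake rises steeply across quartiles
        assert (
            report.table["rice_g_mean"].is_monotonic_increasing
        )
        assert report.trend_p["rice_g"] < 1e-6
        assert report.trend_p["zinc_mg_day[high]"] < 0.05
        text = render_quartile_markdown(report)
        assert "traditional" in text

    def test_unknown_pattern_rejected(self, small_cohort, dri, loadings):
        with pytest.raises(bf.ValidationError):
            bf.quartile_report(
                small_cohort.subjects, loadings, [bf.Scenario("normal", 1.7)],
                dri, "keto",
            )


def test_covariates_frame_shape(small_cohort):
    covs = covariates_from_cohort(small_cohort.subjects)
    assert list(covs.columns) == [
        "age", "sex", "region", "residence", "ses", "education", "energy",
    ]
    assert len(covs) == 80
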