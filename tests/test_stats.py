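"""Welch t, Pearson r, chi-square, and the cohort group report."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from clgfnet.stats import (chi2_2x2, group_report, pearson_r, welch_t,
                           welch_t_summary)


class TestWelchT:
    # demographic rows of the emulated study's Table: printed mean/SD/n
    # reproduce the printed t to 2 dp under Welch's unequal-variance form
    @pytest.mark.parametrize("a,b,expected", [
        ((22.06, 2.11, 17), (23.80, 4.60, 15), -1.35),   # age
        ((14.06, 1.20, 17), (13.27, 2.25, 15), 1.22),    # education
        ((11.35, 1.69, 17), (10.53, 2.59, 15), 1.05),    # handedness
        ((108.35, 17.26, 17), (103.33, 9.90, 15), 1.02), # IQ
    ])
    def test_reproduces_printed_demographics(self, a, b, expected):
        res = welch_t_summary(*a, *b)
        assert round(res.statistic, 2) == expected

    def test_identical_summaries_give_zero(self):
        res = welch_t_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert res.statistic == 0.0

    def test_vectors_match_summary_to_high_precision(self, rng):
        a = rng.normal(0.0, 1.0, 14)
        b = rng.normal(0.3, 2.0, 11)
        r1 = welch_t(a, b)
        r2 = welch_t_summary(a.mean(), a.std(ddof=1), a.size,
                             b.mean(), b.std(ddof=1), b.size)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)
        assert r1.p == pytest.approx(r2.p, rel=1e-12)

    def test_agrees_with_scipy_welch(self, rng):
        a = rng.normal(0.0, 1.0, 20)
        b = rng.normal(0.5, 1.5, 12)
        res = welch_t(a, b)
        t_ref, p_ref = sps.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(t_ref, rel=1e-10)
        assert res.p == pytest.approx(p_ref, rel=1e-10)

    def test_zero_variance_cases(self):
        same = welch_t_summary(2.0, 0.0, 5, 2.0, 0.0, 5)
        assert same.statistic == 0.0 and same.p == 1.0
        diff = welch_t_summary(3.0, 0.0, 5, 2.0, 0.0, 5)
        assert np.isinf(diff.statistic) and diff.p == 0.0

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t_summary(1.0, 1.0, 1, 2.0, 1.0, 5)


class TestPearsonR:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1).estimate == pytest.approx(1.0)
        assert pearson_r(x, -x).estimate == pytest.approx(-1.0)

    def test_affine_rescaling_invariance(self, rng):
        x = rng.standard_normal(25)
        y = rng.standard_normal(25)
        base = pearson_r(x, y)
        scaled = pearson_r(3.0 * x + 7.0, 0.5 * y - 2.0)
        assert scaled.estimate == pytest.approx(base.estimate, rel=1e-12)
        assert scaled.p == pytest.approx(base.p, rel=1e-12)

    def test_p_matches_scipy(self, rng):
        x = rng.standard_normal(15)
        y = x * 0.5 + rng.standard_normal(15)
        res = pearson_r(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert res.estimate == pytest.approx(r_ref, rel=1e-10)
        assert res.p == pytest.approx(p_ref, rel=1e-8)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(5), np.arange(5.0))


class TestChi2:
    def test_balanced_table_gives_zero(self):
        assert chi2_2x2([[10, 10], [10, 10]]).statistic == 0.0

    def test_perfect_split_closed_form(self):
        # chi2 = n for a diagonal 2x2 table
        assert chi2_2x2([[20, 0], [0, 20]]).statistic == pytest.approx(40.0)

    def test_sex_table_computed_value(self):
        # 11/6 vs 12/3 males/females: Pearson chi-square without
        # continuity correction; the source table prints 0.95, which no
        # standard variant reproduces exactly — we report the computed one
        res = chi2_2x2([[11, 6], [12, 3]])
        assert res.statistic == pytest.approx(0.9221, abs=1e-3)
        assert res.df == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi2_2x2([[0, 0], [5, 5]])


class TestGroupReport:
    def _table(self, rng, effect=0.0):
        rows = []
        for g, n in (("control", 8), ("patient", 8)):
            for i in range(n):
                clgf = max(0.0, rng.normal(6 if g == "control" else 6 - effect, 1))
                rows.append({
                    "subject_id": f"{g}{i}", "group": g,
                    "beta_power": rng.normal(1, .1),
                    "gamma_power": rng.normal(1, .1),
                    "beta_plv": rng.uniform(.2, .4),
                    "gamma_plv": rng.uniform(.2, .4),
                    "switch_duration_ms": rng.normal(500, 50),
                    "switch_events": rng.normal(20, 3),
                    "n_pos_fb_total": 10, "n_pos_fb_local": 5,
                    "n_pos_fb_global": 5, "n_clgf": clgf,
                    "panss_negative": 20 - 2 * clgf + rng.normal(0, .5),
                })
        return pd.DataFrame(rows)

    def test_missing_measure_named_in_error(self, rng):
        t = self._table(rng).drop(columns=["beta_plv"])
        with pytest.raises(KeyError, match="beta_plv"):
            group_report(t)

    def test_group_difference_detected(self, rng):
        rep = group_report(self._table(rng, effect=4.0))
        assert rep["measures"]["n_clgf"]["p"] < 0.05
        assert (rep["measures"]["n_clgf"]["control"]["mean"]
                > rep["measures"]["n_clgf"]["patient"]["mean"])

    def test_correlation_panel_tracks_score_model(self, rng):
        rep = group_report(self._table(rng))
        assert rep["correlations"]["panss_negative"]["r"] < -0.8

    def test_report_figures_written(self, rng, tmp_path):
        from clgfnet.plots import correlation_scatter, group_bar_plot
        table = self._table(rng, effect=2.0)
        rep = group_report(table)
        group_bar_plot(rep, ["n_clgf", "beta_power"], tmp_path / "bars.png")
        correlation_scatter(table, "n_clgf", "panss_negative",
                            tmp_path / "scatter.png")
        assert (tmp_path / "bars.png").stat().st_size > 0
        assert (tmp_path / "scatter.png").stat().st_size > 0

    def test_noiseless_score_model_gives_r_minus_one(self, rng):
        t = self._table(rng)
        t["panss_negative"] = 30 - 2.0 * t["n_clgf"]
        rep = group_report(t)
        assert rep["correlations"]["panss_negative"]["r"] == pytest.approx(-1.0)
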