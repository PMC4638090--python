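"""Epidemiology: rates, odds ratios, test dispatch, group-level correlation."""

import numpy as np
import pytest
from scipy import stats

from glycotrial import (
    DataValidationError,
    DomainError,
    InfectionEvent,
    acquired_filter,
    build_report,
    compare_rates,
    group_compare,
    gv_infection_correlation,
    incidence_rate,
    odds_ratio,
)
from glycotrial.analysis import _fisher_exact_rxc


class TestIncidenceRate:
    @pytest.mark.parametrize(
        "events,exposure,scale,expected",
        [
            (7, 460.0, 1000.0, 15.217),
            (10, 392.0, 1000.0, 25.510),
            (7, 424.0, 1000.0, 16.509),
            (22, 546.0, 100.0, 4.029),
            (24, 470.0, 100.0, 5.106),
            (0, 100.0, 1000.0, 0.0),
        ],
    )
    def test_values(self, events, exposure, scale, expected):
        assert incidence_rate(events, exposure, scale).rate == pytest.approx(
            expected, abs=5e-4
        )

    def test_scale_equivariance(self):
        r = incidence_rate(7, 460.0, 1000.0)
        assert r.rescaled(100.0).rate == pytest.approx(r.rate / 10.0)

    def test_zero_exposure_rejected(self):
        with pytest.raises(DomainError):
            incidence_rate(1, 0.0)


class TestOddsRatio:
    def test_trial_2x2(self):
        # infected 23/53 (standard arm) vs 18/52 (study arm)
        res = odds_ratio(23, 30, 18, 34, orientation="B/A")
        assert res.oddsratio == pytest.approx((23 * 34) / (30 * 18), rel=1e-12)
        assert round(res.oddsratio, 1) == 1.4

    def test_symmetric_table_is_one(self):
        assert odds_ratio(5, 5, 5, 5).oddsratio == pytest.approx(1.0)

    def test_woolf_ci_direct_formula(self):
        res = odds_ratio(1, 1, 1, 4)
        assert res.oddsratio == pytest.approx(4.0)
        se = np.sqrt(1 + 1 + 1 + 0.25)
        assert res.ci_low == pytest.approx(4.0 * np.exp(-1.959964 * se), rel=1e-5)
        assert res.ci_high == pytest.approx(4.0 * np.exp(+1.959964 * se), rel=1e-5)

    def test_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import Table2x2

        t = Table2x2(np.array([[23, 30], [18, 34]]))
        res = odds_ratio(23, 30, 18, 34)
        assert res.oddsratio == pytest.approx(t.oddsratio, rel=1e-12)
        lo, hi = t.oddsratio_confint()
        assert res.ci_low == pytest.approx(lo, rel=1e-9)
        assert res.ci_high == pytest.approx(hi, rel=1e-9)

    def test_orientation_inversion(self):
        res = odds_ratio(7, 12, 3, 20, orientation="B/A")
        inv = res.inverse()
        assert res.oddsratio * inv.oddsratio == pytest.approx(1.0)
        assert inv.orientation == "A/B"
        assert inv.ci_low == pytest.approx(1.0 / res.ci_high)

    def test_zero_cell_haldane_flagged(self):
        res = odds_ratio(0, 10, 5, 5)
        assert res.continuity_corrected
        assert res.oddsratio == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))

    def test_zero_margin_undefined(self):
        with pytest.raises(DomainError):
            odds_ratio(0, 0, 5, 5)


class TestCompareRates:
    def test_identical_rates_p_one(self):
        r = incidence_rate(10, 100.0)
        assert compare_rates(r, r) == pytest.approx(1.0)

    def test_degenerate_zero_events(self):
        assert compare_rates(incidence_rate(0, 100.0), incidence_rate(0, 100.0)) == 1.0

    def test_against_exact_conditional_binomial(self):
        # conditional on the total, x1 ~ Binomial(n, T1/(T1+T2)) under H0
        x1, t1, x2, t2 = 10, 392.0, 7, 460.0
        p_score = compare_rates(incidence_rate(x1, t1), incidence_rate(x2, t2))
        n, pr = x1 + x2, t1 / (t1 + t2)
        pmf = stats.binom.pmf(np.arange(n + 1), n, pr)
        p_exact = float(pmf[pmf <= pmf[x1] * (1 + 1e-9)].sum())
        assert p_score == pytest.approx(p_exact, abs=0.08)
        assert (p_score < 0.5) == (p_exact < 0.5)

    def test_against_statsmodels_score_test(self):
        from statsmodels.stats.rates import test_poisson_2indep

        r1, r2 = incidence_rate(10, 392.0), incidence_rate(7, 460.0)
        res = test_poisson_2indep(10, 392.0, 7, 460.0, method="score")
        assert compare_rates(r1, r2) == pytest.approx(res.pvalue, rel=1e-6)


class TestGroupCompare:
    def test_identical_arms_p_near_one(self):
        rng = np.random.default_rng(0)
        v = rng.normal(100, 10, 30)
        res = group_compare({"A": v, "B": v, "C": v}, "continuous", "x")
        assert res.p_value > 0.99

    def test_shifted_arms_power(self):
        # 1-SD shift at n=50: rejection in >80 % of replicates
        rejections = 0
        n_rep = 200
        for i in range(n_rep):
            rng = np.random.default_rng([17, i])
            arms = {
                "A": rng.normal(0.0, 1.0, 50),
                "B": rng.normal(1.0, 1.0, 50),
                "C": rng.normal(0.0, 1.0, 50),
            }
            if group_compare(arms, "continuous").p_value < 0.05:
                rejections += 1
        assert rejections / n_rep > 0.80

    def test_nonnormal_data_uses_kruskal(self):
        rng = np.random.default_rng(3)
        arms = {k: rng.lognormal(0, 1.5, 60) for k in "ABC"}
        res = group_compare(arms, "continuous")
        assert res.test == "kruskal"
        assert res.posthoc and len(res.posthoc) == 3

    def test_normal_data_uses_anova_with_tukey(self):
        rng = np.random.default_rng(4)
        arms = {k: rng.normal(100, 10, 40) for k in "ABC"}
        res = group_compare(arms, "continuous")
        assert res.test == "anova"
        assert set(res.posthoc) == {"A/B", "A/C", "B/C"}

    def test_small_expected_cells_choose_fisher(self):
        table = np.array([[1, 9], [2, 8], [0, 10]])  # expected cells < 5
        res = group_compare(table, "categorical")
        assert res.test == "fisher"

    def test_large_table_uses_chi2(self):
        table = np.array([[20, 30], [25, 25], [30, 20]])
        res = group_compare(table, "categorical")
        assert res.test == "chi2"
        expected = stats.chi2_contingency(table, correction=False)[1]
        assert res.p_value == pytest.approx(expected)

    def test_empty_arm_reported(self):
        with pytest.raises(DataValidationError, match="arm"):
            group_compare({"A": [1.0], "B": [1.0, 2.0]}, "continuous", "x")


class TestFisherExact:
    def test_2x2_matches_scipy(self):
        for table in ([[3, 7], [6, 4]], [[1, 9], [8, 2]], [[0, 5], [5, 0]]):
            mine = _fisher_exact_rxc(np.array(table))
            ref = stats.fisher_exact(np.array(table))[1]
            assert mine == pytest.approx(ref, rel=1e-9), table

    def test_2x3_reference_value(self):
        # frozen from R fisher.test on the same table
        table = np.array([[1, 2, 5], [4, 3, 1]])
        assert _fisher_exact_rxc(table) == pytest.approx(0.1452991, abs=2e-6)


class TestGroupCorrelation:
    def test_collinear(self):
        r, p = gv_infection_correlation([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
        assert r == pytest.approx(1.0)

    def test_anticollinear(self):
        r, _ = gv_infection_correlation([1.0, 2.0, 3.0], [30.0, 20.0, 10.0])
        assert r == pytest.approx(-1.0)

    def test_printed_rounded_triples(self):
        # arm CV (days 1-7) vs tracheobronchitis per 1000 ventilator-days
        r, p = gv_infection_correlation([28.3, 42.6, 28.4], [15.2, 25.5, 16.5])
        assert r == pytest.approx(0.9940, abs=1e-3)
        assert 0 <= p <= 1

    def test_zero_variance_undefined(self):
        with pytest.raises(DomainError):
            gv_infection_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_affine_invariance(self):
        x, y = [1.0, 5.0, 2.0], [3.0, 1.0, 9.0]
        r1, _ = gv_infection_correlation(x, y)
        r2, _ = gv_infection_correlation([10 + 2 * v for v in x], y)
        assert r1 == pytest.approx(r2, rel=1e-12)


class TestAcquiredFilter:
    def test_boundary_48h_inclusive(self):
        evs = [
            InfectionEvent("p", "vap", 47.9),
            InfectionEvent("p", "vap", 48.0),
            InfectionEvent("p", "uti", 100.0),
        ]
        assert [e.onset_h for e in acquired_filter(evs)] == [48.0, 100.0]

    def test_empty_and_all_early(self):
        assert acquired_filter([]) == []
        assert acquired_filter([InfectionEvent("p", "vap", 10.0)]) == []


@pytest.fixture(scope="module")
def report():
    from dataclasses import replace

    from glycotrial import load_design, simulate_trial

    design = load_design()
    arms = tuple(replace(a, n_patients=8) for a in design.arms)
    data = simulate_trial(replace(design, arms=arms, n_centers=2), seed=5)
    return build_report(data)


class TestBuildReport:

    def test_contains_all_tables(self, report):
        assert set(report) == {
            "nutrients",
            "glycemic_control",
            "infections",
            "odds_ratios",
            "correlations",
            "outcomes",
        }

    def test_glycemic_rows_present(self, report):
        rows = set(report["glycemic_control"]["variable"])
        for needed in (
            "capillary_glucose_mgdl",
            "gli_days_1_7",
            "gv_cv_pct_days_1_28",
            "n_hypo_severe",
        ):
            assert needed in rows

    def test_odds_ratios_oriented_both_ways(self, report):
        df = report["odds_ratios"]
        assert set(df["orientation"]) == {"B/A", "C/A", "C/B"}
        assert (df["oddsratio"] * df["oddsratio_inverse"]).round(1).eq(1.0).all()

    def test_empty_arm_is_error(self):
        from glycotrial.io import TrialData
        from glycotrial import PatientRecord

        data = TrialData(
            glucose={},
            patients=[PatientRecord("p1", "A", "C01"), PatientRecord("p2", "B", "C01")],
        )
        with pytest.raises(DataValidationError, match="arm C"):
            build_report(data)


def test_injected_published_counts_reproduce_published_rates():
    """Feeding the printed counts/exposures through the rate and OR operations
    reproduces the printed table values at their printed precision."""
    assert round(incidence_rate(7, 460, 1000).rate, 1) == 15.2
    assert round(incidence_rate(10, 392, 1000).rate, 1) == 25.5
    assert round(incidence_rate(7, 424, 1000).rate, 1) == 16.5
    assert round(incidence_rate(22, 546, 100).rate, 2) == 4.03
    assert round(incidence_rate(24, 470, 100).rate, 2) == 5.11
    assert round(odds_ratio(23, 30, 18, 34).oddsratio, 1) == 1.4
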