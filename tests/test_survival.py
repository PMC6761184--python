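"""Kaplan-Meier, log-rank and Cox proportional hazards against hand oracles."""
import math

import numpy as np
import pandas as pd
import pytest

from infantglioma.config import SurvivalConfig
from infantglioma.models import SurvivalRecord
from infantglioma.survival import (
    EstimationError,
    cox_ph,
    derive_endpoints,
    km_estimate,
    km_median,
    logrank_test,
    survival_at,
)


def rec(i, time, event, group=""):
    return SurvivalRecord(sample_id=f"s{i}", time=time, event=event, group=group)


class TestEndpoints:
    def test_alive_without_progression_censors_both_endpoints(self):
        out = derive_endpoints("p1", dx_years=0.0, last_fu_years=5.0)
        assert (out["OS"].time, out["OS"].event) == (5.0, 0)
        assert (out["PFS"].time, out["PFS"].event) == (5.0, 0)

    def test_progression_then_death(self):
        out = derive_endpoints(
            "p1", dx_years=0.0, last_fu_years=1.9, death_years=1.9, progression_years=1.1
        )
        assert (out["PFS"].time, out["PFS"].event) == (pytest.approx(1.1), 1)
        assert (out["OS"].time, out["OS"].event) == (pytest.approx(1.9), 1)

    def test_missing_diagnosis_date_excluded_with_error(self):
        with pytest.raises(EstimationError):
            derive_endpoints("p1", dx_years=float("nan"), last_fu_years=2.0)


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate([rec(i, 1.0 + i, 0) for i in range(5)])
        assert survival_at(curve, 3.0).survival_pct == 100.0

    def test_two_subject_hand_computation(self):
        curve = km_estimate([rec(0, 1.0, 1), rec(1, 2.0, 1)])
        assert curve.survival == pytest.approx([0.5, 0.0])
        assert survival_at(curve, 1.5).survival_pct == pytest.approx(50.0)

    def test_three_subject_censoring_hand_computation(self):
        # censor at 0.5, events at 1 and 2: S(1) = 1 - 1/2, S(2) = 0
        curve = km_estimate([rec(0, 0.5, 0), rec(1, 1.0, 1), rec(2, 2.0, 1)])
        assert curve.survival == pytest.approx([0.5, 0.0])
        assert curve.at_risk.tolist() == [2, 1]

    def test_greenwood_variance_hand_computation(self):
        # 4 subjects, events at 1 and 2, censored at 3 and 4
        curve = km_estimate([rec(0, 1.0, 1), rec(1, 2.0, 1), rec(2, 3.0, 0), rec(3, 4.0, 0)])
        s1, s2 = 3 / 4, 3 / 4 * 2 / 3
        v1 = s1**2 * (1 / (4 * 3))
        v2 = s2**2 * (1 / (4 * 3) + 1 / (3 * 2))
        assert curve.survival == pytest.approx([s1, s2])
        assert curve.variance == pytest.approx([v1, v2])

    def test_matches_lifelines_survival_function(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(3)
        times = rng.exponential(2.0, 60)
        events = rng.integers(0, 2, 60)
        if not events.any():
            events[0] = 1
        records = [rec(i, float(t), int(e)) for i, (t, e) in enumerate(zip(times, events))]
        curve = km_estimate(records)
        km = KaplanMeierFitter().fit(times, events)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(
                float(km.survival_function_at_times(t).iloc[0]), abs=1e-10
            )

    def test_log_scale_confidence_bands(self):
        curve = km_estimate([rec(i, float(t), 1) for i, t in enumerate([1, 2, 3, 4, 5, 6, 7, 8])])
        # first event: S = 7/8, Var = S^2 * 1/(8*7)
        s, v = 7 / 8, (7 / 8) ** 2 / 56
        se_log = math.sqrt(v) / s
        assert curve.ci_lower[0] == pytest.approx(s * math.exp(-1.959964 * se_log), abs=1e-6)
        assert np.all(curve.ci_upper <= 1.0) and np.all(curve.ci_lower >= 0.0)

    def test_loglog_bands_selectable(self):
        cfg = SurvivalConfig(ci_transform="loglog")
        curve = km_estimate([rec(i, float(i + 1), 1) for i in range(8)], cfg)
        assert np.all(curve.ci_upper <= 1.0) and np.all(curve.ci_lower >= 0.0)

    def test_evaluation_beyond_follow_up_is_flagged(self):
        curve = km_estimate([rec(0, 1.0, 1), rec(1, 2.0, 1)])
        point = survival_at(curve, 10.0)
        assert point.truncated and point.survival_pct == 0.0

    def test_time_zero_is_certain_survival(self):
        curve = km_estimate([rec(0, 1.0, 1)])
        assert survival_at(curve, 0.0).survival_pct == 100.0

    def test_order_invariance(self):
        records = [rec(i, float(t), e) for i, (t, e) in enumerate([(3, 1), (1, 1), (2, 0), (5, 1)])]
        a = km_estimate(records)
        b = km_estimate(records[::-1])
        assert a.survival == pytest.approx(b.survival)


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        g = [rec(0, 1.0, 1), rec(1, 2.0, 1)]
        h = [rec(2, 1.0, 1, "B"), rec(3, 2.0, 1, "B")]
        out = logrank_test({"A": g, "B": h})
        assert out["chi_square"] == pytest.approx(0.0, abs=1e-12)
        assert out["p_value"] == pytest.approx(1.0)
        assert out["df"] == 1

    def test_four_subject_hand_computation(self):
        # A events at 1,2; B events at 3,4; O-E = 7/6, V = 17/36
        out = logrank_test(
            {
                "A": [rec(0, 1.0, 1), rec(1, 2.0, 1)],
                "B": [rec(2, 3.0, 1), rec(3, 4.0, 1)],
            }
        )
        expected = (7 / 6) ** 2 / (17 / 36)
        assert out["chi_square"] == pytest.approx(expected, rel=1e-9)

    def test_single_group_is_an_error(self):
        with pytest.raises(EstimationError):
            logrank_test({"A": [rec(0, 1.0, 1)]})


def _grid_search_cox(times, events, x, grid=None):
    """Brute-force maximization of the Cox partial likelihood (no ties)."""
    if grid is None:
        grid = np.arange(-4.0, 4.0, 1e-4)
    order = np.argsort(times)
    times, events, x = times[order], events[order], x[order]
    best_beta, best_ll = None, -np.inf
    for beta in grid:
        ll = 0.0
        for i in range(len(times)):
            if events[i] != 1:
                continue
            risk = x[i:]  # all with time >= t_i
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * risk)))
        if ll > best_ll:
            best_ll, best_beta = ll, beta
    return best_beta


class TestCox:
    def test_matches_partial_likelihood_grid_search(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.ones(6, dtype=int)
        x = np.array([1.0, 0.0, 1.0, 0.0, 0.0, 1.0])
        records = [rec(i, float(t), 1) for i, t in enumerate(times)]
        cov = pd.DataFrame({"x": x}, index=[f"s{i}" for i in range(6)])
        fit = cox_ph(records, cov)
        oracle = _grid_search_cox(times, events, x)
        assert fit.loc["x", "coef"] == pytest.approx(oracle, abs=1e-3)
        assert fit.loc["x", "hr"] == pytest.approx(math.exp(oracle), rel=2e-3)

    def test_null_covariate_hazard_ratio_near_one(self):
        rng = np.random.default_rng(1)
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0, n)
        records = [rec(i, float(t[i]), 1) for i in range(n)]
        cov = pd.DataFrame({"x": x}, index=[f"s{i}" for i in range(n)])
        fit = cox_ph(records, cov)
        assert 0.9 <= fit.loc["x", "hr"] <= 1.1
        assert fit.loc["x", "wald_p"] > 0.01

    def test_no_events_is_an_estimation_error(self):
        records = [rec(i, 1.0 + i, 0) for i in range(5)]
        cov = pd.DataFrame({"x": [0, 1, 0, 1, 0]}, index=[f"s{i}" for i in range(5)])
        with pytest.raises(EstimationError):
            cox_ph(records, cov)


class TestKmMedian:
    def test_exponential_median_recovery(self):
        rng = np.random.default_rng(9)
        times = rng.exponential(2.0 / math.log(2.0), 5000)
        curve = km_estimate([rec(i, float(t), 1) for i, t in enumerate(times)])
        assert km_median(curve) == pytest.approx(2.0, abs=0.1)

    def test_median_nan_when_not_reached(self):
        curve = km_estimate([rec(0, 1.0, 1)] + [rec(i, 2.0, 0) for i in range(1, 6)])
        assert math.isnan(km_median(curve))
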