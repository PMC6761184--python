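"""Endpoint derivation and survival statistics.

Endpoints follow the clinical definitions: overall survival (OS) runs from
diagnosis to death or last follow-up; progression-free survival (PFS) runs
from diagnosis to the first progression requiring a change in clinical
management, censored at last follow-up. PFS times never exceed OS times.

The Kaplan-Meier estimator is implemented directly (product-limit with
Greenwood variance) so the confidence-band transform is explicit: the
default 95% bands are computed on the log-survival scale, matching the
default of the R ``survival`` machinery (log-log selectable). Log-rank and
Cox proportional-hazards (Efron tie handling, Wald tests) are provided by
lifelines behind this module's interface.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test

from .config import SurvivalConfig
from .models import SurvivalRecord

Z_95 = 1.959963984540054


class EstimationError(ValueError):
    """The requested statistic cannot be estimated from the data."""


@dataclass
class SurvivalCurve:
    """Right-continuous product-limit estimate with Greenwood variance."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) immediately after each event time
    variance: np.ndarray  # Greenwood variance of S(t)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    max_follow_up: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise AssertionError("survival function must be non-increasing")


@dataclass
class PointEstimate:
    time: float
    survival_pct: float
    ci_lower_pct: float
    ci_upper_pct: float
    truncated: bool = False

    def format(self) -> str:
        return (
            f"{self.survival_pct:.1f}% ({self.ci_lower_pct:.1f}"
            f"–{self.ci_upper_pct:.1f}%)"
        )


def derive_endpoints(
    sample_id: str,
    dx_years: float,
    last_fu_years: float,
    death_years: Optional[float] = None,
    progression_years: Optional[float] = None,
    group: str = "",
) -> Dict[str, SurvivalRecord]:
    """OS and PFS records from per-patient event chronology (years from an
    arbitrary common origin). Raises when the diagnosis time is missing."""
    if dx_years is None or (isinstance(dx_years, float) and math.isnan(dx_years)):
        raise EstimationError(f"{sample_id}: missing diagnosis date")
    end = death_years if death_years is not None else last_fu_years
    os_rec = SurvivalRecord(
        sample_id=sample_id,
        time=end - dx_years,
        event=int(death_years is not None),
        endpoint="OS",
        group=group,
    )
    if progression_years is not None:
        pfs_time, pfs_event = progression_years - dx_years, 1
    else:
        pfs_time, pfs_event = os_rec.time, os_rec.event
    if pfs_time > os_rec.time:
        raise EstimationError(f"{sample_id}: progression recorded after OS endpoint")
    pfs_rec = SurvivalRecord(
        sample_id=sample_id, time=pfs_time, event=pfs_event, endpoint="PFS", group=group
    )
    return {"OS": os_rec, "PFS": pfs_rec}


def km_estimate(
    records: Sequence[SurvivalRecord], cfg: Optional[SurvivalConfig] = None
) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate with Greenwood variance and 95% bands."""
    cfg = cfg or SurvivalConfig()
    if not records:
        raise EstimationError("no records")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    event_times: List[float] = []
    surv: List[float] = []
    greenwood_sum = 0.0
    var: List[float] = []
    at_risk: List[int] = []
    d_list: List[int] = []
    s = 1.0
    n = len(times)
    i = 0
    while i < n:
        t = times[i]
        j = i
        d = 0
        while j < n and times[j] == t:
            d += int(events[j])
            j += 1
        r = n - i  # at risk just before t
        if d > 0:
            s *= 1.0 - d / r
            if r > d:
                greenwood_sum += d / (r * (r - d))
            else:
                greenwood_sum = math.inf
            event_times.append(t)
            surv.append(s)
            var.append(s * s * greenwood_sum if math.isfinite(greenwood_sum) else 0.0)
            at_risk.append(r)
            d_list.append(d)
        i = j

    surv_arr = np.array(surv)
    var_arr = np.array(var)
    lower, upper = _confidence_bands(surv_arr, var_arr, cfg.ci_transform)
    return SurvivalCurve(
        times=np.array(event_times),
        survival=surv_arr,
        variance=var_arr,
        ci_lower=lower,
        ci_upper=upper,
        at_risk=np.array(at_risk),
        events=np.array(d_list),
        max_follow_up=float(times.max()),
    )


def _confidence_bands(surv: np.ndarray, var: np.ndarray, transform: str) -> tuple:
    """95% bands on the log-survival (default) or log(-log) scale, clipped to [0,1]."""
    lower = np.zeros_like(surv)
    upper = np.ones_like(surv)
    with np.errstate(divide="ignore", invalid="ignore"):
        for i, (s, v) in enumerate(zip(surv, var)):
            if s <= 0.0:
                lower[i] = upper[i] = 0.0
                continue
            se_log = math.sqrt(v) / s  # delta method: se of log S
            if transform == "log":
                lower[i] = s * math.exp(-Z_95 * se_log)
                upper[i] = s * math.exp(Z_95 * se_log)
            else:  # log-log
                if s >= 1.0:
                    lower[i], upper[i] = s, s
                    continue
                theta = math.log(-math.log(s))
                se_theta = se_log / abs(math.log(s))
                lower[i] = math.exp(-math.exp(theta + Z_95 * se_theta))
                upper[i] = math.exp(-math.exp(theta - Z_95 * se_theta))
    return np.clip(lower, 0.0, 1.0), np.clip(upper, 0.0, 1.0)


def survival_at(curve: SurvivalCurve, t: float) -> PointEstimate:
    """Step-function evaluation (right-continuous) with the 95% CI, in percent."""
    if t < 0:
        raise ValueError("t must be non-negative")
    idx = np.searchsorted(curve.times, t, side="right") - 1
    truncated = t > curve.max_follow_up
    if idx < 0:
        return PointEstimate(t, 100.0, 100.0, 100.0, truncated)
    return PointEstimate(
        time=t,
        survival_pct=100.0 * float(curve.survival[idx]),
        ci_lower_pct=100.0 * float(curve.ci_lower[idx]),
        ci_upper_pct=100.0 * float(curve.ci_upper[idx]),
        truncated=truncated,
    )


def km_median(curve: SurvivalCurve) -> float:
    """Smallest event time where S(t) <= 0.5 (NaN when never reached)."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    if len(below) == 0:
        return float("nan")
    return float(curve.times[below[0]])


def logrank_test(groups: Dict[str, Sequence[SurvivalRecord]]) -> dict:
    """K-sample log-rank test (observed minus expected, hypergeometric variance)."""
    if len(groups) < 2:
        raise EstimationError("log-rank test requires >= 2 groups")
    rows = []
    for label, records in groups.items():
        if not records:
            raise EstimationError(f"group {label!r} has no records")
        for rec in records:
            rows.append((rec.time, rec.event, label))
    frame = pd.DataFrame(rows, columns=["time", "event", "label"])
    result = multivariate_logrank_test(frame["time"], frame["label"], frame["event"])
    return {
        "chi_square": float(result.test_statistic),
        "df": int(len(groups) - 1),
        "p_value": float(result.p_value),
    }


def cox_ph(
    records: Sequence[SurvivalRecord],
    covariates: pd.DataFrame,
    cfg: Optional[SurvivalConfig] = None,
) -> pd.DataFrame:
    """Cox proportional hazards (partial likelihood, Efron ties, Wald tests).

    ``covariates`` is indexed by sample_id with numeric columns. Returns one
    row per covariate: coef, HR, 95% CI, SE, Wald p. Raises
    :class:`EstimationError` when there are no events or the partial
    likelihood is monotone (complete separation).
    """
    cfg = cfg or SurvivalConfig()
    if not any(r.event for r in records):
        raise EstimationError("no events: the partial likelihood is flat")
    frame = covariates.copy()
    ids = [r.sample_id for r in records]
    frame = frame.loc[ids]
    frame["time"] = [r.time for r in records]
    frame["event"] = [r.event for r in records]
    fitter = CoxPHFitter()
    try:
        fitter.fit(frame, duration_col="time", event_col="event")
    except Exception as err:  # lifelines ConvergenceError and friends
        raise EstimationError(f"Cox estimation failed: {err}") from err
    summary = fitter.summary
    return pd.DataFrame(
        {
            "coef": summary["coef"],
            "hr": summary["exp(coef)"],
            "hr_ci_lower": summary["exp(coef) lower 95%"],
            "hr_ci_upper": summary["exp(coef) upper 95%"],
            "se": summary["se(coef)"],
            "wald_p": summary["p"],
        }
    )
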