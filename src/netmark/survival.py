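"""Kaplan-Meier estimation and log-rank comparison of expression strata.

Subjects are dichotomised at the median expression of the stratifying
gene (strictly above the median -> high; ties at the median -> low).  The
survival function of each stratum is estimated by the product-limit
(Kaplan-Meier) method, optionally administratively censored at a horizon
(e.g. 3 or 5 years), and the strata are compared with the standard
log-rank test.  The hazard ratio is summarised from the log-rank
observed/expected table as (O1/E1)/(O2/E2) — the univariate, single-gene
summary used for expression-stratified survival plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "KMCurve",
    "GroupComparison",
    "stratify_by_median",
    "km_curve",
    "logrank",
    "compare_by_median",
]


@dataclass
class KMCurve:
    event_times: np.ndarray  # distinct event times, ascending
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )


@dataclass
class GroupComparison:
    logrank_chi2: float
    p: float
    hazard_ratio: float
    observed: tuple[float, float]
    expected: tuple[float, float]
    horizon: float | None = None


def stratify_by_median(table: pd.DataFrame) -> pd.Series:
    """Label each subject 'high' (expression strictly above the median) or
    'low' (at or below — ties go low, deterministically)."""
    if len(table) < 4:
        raise ValueError("need at least 4 subjects to stratify")
    expr = table["expression"].to_numpy(dtype=float)
    if np.all(expr == expr[0]):
        raise ValueError("all expression values identical; cannot stratify")
    med = float(np.median(expr))
    return pd.Series(
        np.where(expr > med, "high", "low"), index=table.index, name="stratum"
    )


def _censor_at(times, events, horizon):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if horizon is not None:
        if horizon <= 0:
            raise ValueError("horizon must be > 0")
        e = np.where(t > horizon, 0, e)
        t = np.minimum(t, horizon)
    return t, e


def km_curve(times, events, horizon: float | None = None) -> KMCurve:
    """Product-limit estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    ``horizon`` administratively censors all follow-up beyond it before
    estimation.  Censored subjects leave the risk set at their censoring
    time but contribute no event.
    """
    t, e = _censor_at(times, events, horizon)
    if t.size == 0:
        raise ValueError("no subjects")
    if np.any(t <= 0):
        raise ValueError("times must be > 0")
    event_times = np.unique(t[e == 1])
    at_risk = np.array([(t >= et).sum() for et in event_times], dtype=float)
    d = np.array([((t == et) & (e == 1)).sum() for et in event_times], dtype=float)
    surv = np.cumprod(1.0 - d / at_risk) if event_times.size else np.array([])
    return KMCurve(
        event_times=event_times, at_risk=at_risk, events=d, survival=surv
    )


def logrank(
    group1: pd.DataFrame, group2: pd.DataFrame, horizon: float | None = None
) -> GroupComparison:
    """Two-sample log-rank test with O/E hazard-ratio summary.

    At each distinct event time the observed events in group 1 are
    compared with the expectation under a common hazard; the chi-square
    statistic (1 df) is (sum O1 - sum E1)^2 / sum Var.  HR =
    (O1/E1)/(O2/E2).
    """
    if len(group1) == 0 or len(group2) == 0:
        raise ValueError("both groups must be non-empty")
    t1, e1 = _censor_at(group1["time"], group1["event"], horizon)
    t2, e2 = _censor_at(group2["time"], group2["event"], horizon)
    if e1.sum() + e2.sum() == 0:
        raise ValueError("no events observed; log-rank undefined")

    all_event_times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    var = 0.0
    O1 = O2 = E1 = E2 = 0.0
    for et in all_event_times:
        n1 = float((t1 >= et).sum())
        n2 = float((t2 >= et).sum())
        d1 = float(((t1 == et) & (e1 == 1)).sum())
        d2 = float(((t2 == et) & (e2 == 1)).sum())
        n, d = n1 + n2, d1 + d2
        if n == 0:
            continue
        exp1 = d * n1 / n
        O1 += d1
        O2 += d2
        E1 += exp1
        E2 += d * n2 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    chi2_stat = 0.0 if var == 0 else (O1 - E1) ** 2 / var
    p = float(chi2.sf(chi2_stat, df=1))
    if E1 == 0 or E2 == 0 or O2 == 0:
        hr = np.inf if O1 > 0 else np.nan
    else:
        hr = (O1 / E1) / (O2 / E2)
    return GroupComparison(
        logrank_chi2=float(chi2_stat),
        p=p,
        hazard_ratio=float(hr),
        observed=(O1, O2),
        expected=(E1, E2),
        horizon=horizon,
    )


def compare_by_median(
    table: pd.DataFrame, horizon: float | None = None
) -> tuple[GroupComparison, KMCurve, KMCurve]:
    """Median-stratified KM comparison: returns (log-rank comparison,
    high-stratum curve, low-stratum curve).  HR is high vs low."""
    strata = stratify_by_median(table)
    high = table[strata == "high"]
    low = table[strata == "low"]
    cmp_ = logrank(high, low, horizon=horizon)
    km_high = km_curve(high["time"], high["event"], horizon=horizon)
    km_low = km_curve(low["time"], low["event"], horizon=horizon)
    return cmp_, km_high, km_low
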