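"""Kaplan-Meier estimation and log-rank comparison across subtypes.

Estimation follows the standard product-limit conventions: censored
observations tied with an event time remain at risk for that time (deaths
processed before censorings), and the k-group log-rank statistic uses
hypergeometric expected events per group at each distinct event time with
df = k - 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = ["KMCurve", "km_curve", "survival_at", "logrank_test"]


@dataclass
class KMCurve:
    """Right-continuous product-limit step function.

    ``event_times`` are the distinct times with >= 1 event; ``survival``
    holds S(t) just after each; ``at_risk`` the risk-set size at each.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int

    def __call__(self, t: float) -> float:
        return survival_at(self, t)


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier estimate from times and event flags (1=event, 0=censored)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one record")
    if (times < 0).any() or not np.isfinite(times).all():
        raise ValueError("times must be finite and nonnegative")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("event flags must be 0 or 1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    # distinct event times only; the survival curve is flat at censorings
    ev = np.unique(times[events == 1])
    surv = np.array([float(kmf.predict(t)) for t in ev])
    event_table = kmf.event_table
    at_risk = np.array([int(event_table.loc[t, "at_risk"]) for t in ev])
    return KMCurve(event_times=ev, survival=surv, at_risk=at_risk, n=int(times.size))


def survival_at(curve: KMCurve, t: float) -> float:
    """Step-function evaluation S(t): the value after the last event time <= t."""
    if t < 0:
        raise ValueError("time must be nonnegative")
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    if idx < 0:
        return 1.0
    return float(curve.survival[idx])


def logrank_test(times, events, groups):
    """k-group log-rank test; returns (chi-square statistic, df, p-value)."""
    df = pd.DataFrame({
        "time": np.asarray(times, dtype=float),
        "event": np.asarray(events, dtype=int),
        "group": np.asarray(groups),
    })
    labels = df["group"].unique()
    if len(labels) < 2:
        raise ValueError("need at least 2 non-empty groups")
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return float(res.test_statistic), int(len(labels) - 1), float(res.p_value)
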