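"""Kaplan-Meier survival estimation for tumor cohorts and risk strata.

Product-limit estimation of overall and disease-specific survival with the
study conventions: time measured in days from primary diagnosis,
administrative censoring at the 5-year follow-up cap (1826 days), events
preceding censorings at tied times, survival-at-time and median-survival
summaries. Estimation is delegated to lifelines' ``KaplanMeierFitter``;
this module fixes the container and the evaluation conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

FOLLOW_UP_CAP_DAYS = 1826  # 5 years
DAYS_PER_YEAR = 365.25

__all__ = [
    "KMCurve",
    "km_estimate",
    "survival_at",
    "median_survival",
    "km_by_stratum",
    "FOLLOW_UP_CAP_DAYS",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve.

    ``times`` are the distinct event times t_1 < ... < t_m; ``survival``
    the estimate S(t_j) just after each; ``n_at_risk``/``n_events`` the
    risk-set size and event count at each t_j. ``max_time`` is the largest
    observed time (event or censoring); evaluation beyond it is flagged.
    """

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_total: int
    max_time: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")


def km_estimate(time_days, event) -> KMCurve:
    """Kaplan-Meier estimate S(t) = prod_{t_j <= t} (1 - d_j / n_j).

    ``time_days`` non-negative times, ``event`` True for an observed event,
    False for right-censoring. At tied times events are handled before
    censorings (censored subjects at t remain in the risk set for events
    at t), the standard convention.
    """
    from lifelines import KaplanMeierFitter

    t = np.asarray(time_days, dtype=float)
    e = np.asarray(event, dtype=bool)
    if t.size == 0:
        raise ValueError("need at least one record")
    if (t < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    tbl = kmf.event_table
    ev = tbl[tbl["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[ev.index, "KM_estimate"].to_numpy(dtype=float)
    return KMCurve(
        times=times,
        survival=surv,
        n_at_risk=ev["at_risk"].to_numpy(dtype=int),
        n_events=ev["observed"].to_numpy(dtype=int),
        n_total=int(t.size),
        max_time=float(t.max()),
    )


def survival_at(curve: KMCurve, t_days: float) -> float:
    """Right-continuous step-function evaluation S(t).

    Returns 1 before the first event. Evaluation beyond the last observed
    time returns the last value but emits a warning, since subjects may
    still have been at risk.
    """
    if t_days < 0:
        raise ValueError("t must be non-negative")
    if t_days > curve.max_time:
        warnings.warn(
            f"evaluating S at t={t_days} beyond last observed time "
            f"{curve.max_time}; returning last value", stacklevel=2)
    idx = np.searchsorted(curve.times, t_days, side="right") - 1
    if idx < 0:
        return 1.0
    return float(curve.survival[idx])


def median_survival(curve: KMCurve) -> float | None:
    """Smallest t with S(t) <= 0.5, or None when the median is not reached."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    if below.size == 0:
        return None
    return float(curve.times[below[0]])


def km_by_stratum(records: pd.DataFrame, endpoint: str = "OS") -> dict[str, KMCurve]:
    """Per-stratum curves from a long-format survival table.

    ``records`` needs columns ``stratum, endpoint, time_days, event``; rows
    with the requested endpoint are grouped by stratum.
    """
    sub = records[records["endpoint"] == endpoint]
    if sub.empty:
        raise ValueError(f"no records with endpoint {endpoint!r}")
    return {
        str(name): km_estimate(g["time_days"], g["event"])
        for name, g in sub.groupby("stratum")
    }


def curve_frame(curve: KMCurve) -> pd.DataFrame:
    """Curve as a tidy table (time_days, time_years, survival, at-risk, events)."""
    return pd.DataFrame({
        "time_days": curve.times,
        "time_years": curve.times / DAYS_PER_YEAR,
        "survival": curve.survival,
        "n_at_risk": curve.n_at_risk,
        "n_events": curve.n_events,
    })
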