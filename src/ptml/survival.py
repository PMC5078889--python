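"""Associating PTML class with outcome: Kaplan–Meier and the log-rank test.

Estimation is delegated to lifelines; this module fixes the conventions the
association report relies on: the product-limit estimator, median survival
defined as the earliest time at which fractional survival reaches 50%
("undefined" when the curve never falls that far within follow-up), events
preceding censorings at tied times, and the unweighted two-group log-rank
statistic referred to a 1-df chi-square distribution.

Multivariate Cox adjustment (e.g. for LDH, age, gender, M stage) is out of
scope here; :func:`survival_table` produces the tidy (time, event, group)
frame that standard survival software — lifelines ``CoxPHFitter`` or the R
``survival`` package — consumes directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .scoring import HIGH, LOW, PTMLResult

#: Distinguished value for an undefined Kaplan–Meier median.
UNDEFINED = None


@dataclass(frozen=True)
class KMCurve:
    """Product-limit curve sampled at its distinct event times."""

    event_times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]
    n_events: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b < a for a, b in zip(self.event_times, self.event_times[1:])):
            raise ValueError("event times must be increasing")
        if any(b > a for a, b in zip(self.survival, self.survival[1:])):
            raise ValueError("survival must be non-increasing")


def survival_table(
    sample_ids: Sequence[str],
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence[str],
) -> pd.DataFrame:
    """Validated tidy table: sample_id, time (days), event (1/0), group."""
    frame = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "time": np.asarray(times, dtype=float),
            "event": np.asarray(events, dtype=int),
            "group": list(groups),
        }
    )
    _validate_times_events(frame["time"].to_numpy(), frame["event"].to_numpy())
    return frame


def _validate_times_events(times: np.ndarray, events: np.ndarray) -> None:
    if times.size == 0:
        raise ValueError("at least one subject is required")
    if np.any(times < 0):
        raise ValueError("survival times must be non-negative")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("event indicators must be 0 (censored) or 1 (event)")


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan–Meier product-limit estimate S(t) = prod (1 - d_i / n_i).

    A censoring tied with an event leaves the subject in that time's risk
    set (event precedes censoring, the standard convention).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    _validate_times_events(t, e)
    fitter = KaplanMeierFitter()
    fitter.fit(t, event_observed=e)
    table = fitter.event_table
    event_rows = table[table["observed"] > 0]
    event_times = tuple(float(x) for x in event_rows.index)
    survival = tuple(
        float(fitter.survival_function_at_times(x).iloc[0]) for x in event_times
    )
    return KMCurve(
        event_times=event_times,
        survival=survival,
        at_risk=tuple(int(x) for x in event_rows["at_risk"]),
        n_events=tuple(int(x) for x in event_rows["observed"]),
    )


def median_survival(curve: KMCurve) -> Optional[float]:
    """Smallest event time at which survival falls to 50% or below.

    Returns the distinguished undefined value (None) when survival exceeds
    50% at the longest observed time point.
    """
    for t, s in zip(curve.event_times, curve.survival):
        if s <= 0.5:
            return t
    return UNDEFINED


def logrank_test(table: pd.DataFrame) -> tuple[float, float]:
    """Unweighted two-group log-rank test on a survival table.

    Returns the chi-square statistic (sum O - E squared over the
    hypergeometric variance) and its two-sided p-value from the 1-df
    chi-square reference distribution.

    Raises
    ------
    ValueError
        If the table does not contain exactly two non-empty groups, or no
        event was observed (statistic undefined).
    """
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"log-rank test requires exactly two groups, found {groups}")
    a = table[table["group"] == groups[0]]
    b = table[table["group"] == groups[1]]
    if a.empty or b.empty:
        raise ValueError("both groups must be non-empty")
    if int(table["event"].sum()) == 0:
        raise ValueError("log-rank statistic is undefined with zero events")
    result = _lifelines_logrank(
        a["time"].to_numpy(),
        b["time"].to_numpy(),
        event_observed_A=a["event"].to_numpy(),
        event_observed_B=b["event"].to_numpy(),
    )
    return float(result.test_statistic), float(result.p_value)


def _curve_dict(curve: KMCurve) -> dict:
    return {
        "event_times": list(curve.event_times),
        "survival": list(curve.survival),
        "at_risk": list(curve.at_risk),
        "n_events": list(curve.n_events),
    }


def ptml_outcome_report(
    scores: Sequence[PTMLResult],
    outcomes: pd.DataFrame,
    threshold: int = 100,
) -> dict:
    """Join PTML classes to outcomes and test the class–survival association.

    ``outcomes`` needs columns ``sample_id``, ``time`` (days) and ``event``
    (1 = observed, 0 = censored).  Samples present on only one side are
    reported under ``unmatched``, never silently dropped.  The report holds
    per-group n, KM curve points, median_50 (None when undefined), and the
    log-rank chi-square and p-value; it is JSON-serializable.
    """
    class_by_sample = {r.sample_id: r.ptml_class for r in scores}
    outcome_ids = set(outcomes["sample_id"])
    unmatched_scores = sorted(set(class_by_sample) - outcome_ids)
    unmatched_outcomes = sorted(outcome_ids - set(class_by_sample))

    joined = outcomes[outcomes["sample_id"].isin(class_by_sample)].copy()
    joined["group"] = joined["sample_id"].map(class_by_sample)
    table = survival_table(
        joined["sample_id"], joined["time"], joined["event"], joined["group"]
    )
    present = sorted(table["group"].unique())
    if len(present) < 2:
        raise ValueError(
            f"survival association needs both PTML classes; only {present} present"
        )

    per_group = {}
    for group in present:
        sub = table[table["group"] == group]
        curve = km_estimate(sub["time"], sub["event"])
        per_group[group] = {
            "n": int(len(sub)),
            "n_events": int(sub["event"].sum()),
            "median_50": median_survival(curve),
            "curve": _curve_dict(curve),
        }
    chi2, p = logrank_test(table)
    return {
        "threshold": threshold,
        "groups": per_group,
        "logrank_chi_square": chi2,
        "logrank_p_value": p,
        "unmatched": {"scores": unmatched_scores, "outcomes": unmatched_outcomes},
    }


def read_outcomes(path: str | Path) -> pd.DataFrame:
    """Read an outcome TSV with columns sample_id, time_days (or time), event."""
    frame = pd.read_csv(path, sep="\t")
    if "time_days" in frame.columns:
        frame = frame.rename(columns={"time_days": "time"})
    missing = {"sample_id", "time", "event"} - set(frame.columns)
    if missing:
        raise ValueError(f"outcome table {path} lacks column(s): {sorted(missing)}")
    frame["sample_id"] = frame["sample_id"].astype(str)
    return frame
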