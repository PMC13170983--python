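"""Remission maintenance: censoring-rule classification, Kaplan–Meier
estimation, and beyond-follow-up extrapolation.

Remission is anchored at the 12-month assessment (year 1). Maintenance is a
discrete annual time-to-relapse process: relapse can be recorded at the year
2-5 assessments and is absorbing (later re-remissions are not recognised).
Missing annual records follow a specific rule: a missing year is deemed the
relapse year when the next available record shows relapse; otherwise the
participant is censored at the first year with no further record.

The arm-level remission proportion is the product of the arm's 12-month
remission proportion and the product-limit maintenance estimate among
remitters. Beyond year 5 the proportion is assumed to keep declining at the
geometric rate observed between years 1 and 5, and remission does not persist
beyond a 10-year cap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import Cohort, ConfigurationError, FOLLOWUP_YEARS, ParticipantRecord

__all__ = ["RemissionHistory", "RemissionSchedule", "classify_history", "km_remission", "extrapolate"]


@dataclass
class RemissionHistory:
    """Event/censoring classification of one 12-month remitter.

    ``reason`` distinguishes censoring at a missing annual record ("missing":
    the participant's information truly ends at ``time - 1``, so they leave the
    risk set before relapses recorded at ``time``) from administrative
    censoring in remission at the end of follow-up ("end": the year-``time``
    assessment was observed, so they remain at risk through ``time``).
    """

    id: str
    time: int            # year index of relapse or censoring (2..5)
    event: bool          # True = relapse observed (possibly deemed, at a missing year)
    reason: str = ""     # for censorings: "missing" | "end"

    @property
    def km_duration(self) -> float:
        """Duration used by the product-limit fit (see ``reason``)."""
        if self.event or self.reason == "end":
            return float(self.time)
        return self.time - 0.5


@dataclass
class RemissionSchedule:
    """Arm-level proportion in remission at each annual cycle.

    ``S[t-1]`` is the proportion of the arm cohort in remission during year t.
    After :func:`extrapolate`, the schedule extends to ``cap_years``; the
    proportion is exactly 0 for any year beyond the cap.
    """

    S: np.ndarray
    cap_years: int = 10
    extrapolation_rate: float | None = None

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        if ((self.S < -1e-12) | (self.S > 1 + 1e-12)).any():
            raise ConfigurationError("remission proportions must lie in [0, 1]")
        if (np.diff(self.S) > 1e-9).any():
            raise ConfigurationError("remission schedule must be non-increasing")

    def proportion(self, year: int) -> float:
        """Proportion in remission during follow-up year ``year`` (1-based)."""
        if year > self.cap_years or year > len(self.S):
            return 0.0
        return float(self.S[year - 1])

    def scaled(self, factor: float) -> "RemissionSchedule":
        if not (0.0 <= factor <= 1.0):
            raise ConfigurationError(f"remission scale must be in [0, 1]; got {factor}")
        return RemissionSchedule(self.S * factor, self.cap_years, self.extrapolation_rate)

    def to_frame(self, arm: str) -> pd.DataFrame:
        return pd.DataFrame({"arm": arm, "year": np.arange(1, len(self.S) + 1),
                             "proportion": self.S})


def classify_history(record: ParticipantRecord) -> RemissionHistory | None:
    """Apply the missing-record rules to one participant's annual statuses.

    Returns None for participants not in remission at 12 months (they never
    enter the at-risk set). Relapse recorded after an earlier recorded relapse
    triggers a validation warning and is ignored (absorbing state).
    """
    if not record.remission_12m:
        return None
    statuses = [record.annual_status.get(y, "missing") for y in range(2, FOLLOWUP_YEARS + 1)]

    def _event(year, idx):
        # later remission after a recorded relapse is contradictory; warn, ignore
        if any(s == "in_remission" for s in statuses[idx + 1:]):
            warnings.warn(
                f"participant {record.id}: remission recorded after relapse at year {year}; ignored"
            )
        return RemissionHistory(record.id, year, True)

    for idx, st in enumerate(statuses):
        year = idx + 2
        if st == "relapsed":
            return _event(year, idx)
        if st == "in_remission":
            continue
        # missing: deemed relapsed here iff the next available record shows relapse
        later = statuses[idx + 1:]
        recorded = [s for s in later if s != "missing"]
        if recorded and recorded[0] == "relapsed":
            return _event(year, idx)
        if not recorded:
            return RemissionHistory(record.id, year, False, reason="missing")
        # bridged by a later in_remission record; continue scanning
    return RemissionHistory(record.id, FOLLOWUP_YEARS, False, reason="end")  # in remission at last record


def km_remission(cohort_arm: Cohort) -> RemissionSchedule:
    """Arm-level remission schedule for years 1-5 by product-limit estimation.

    S(1) is the observed 12-month remission proportion; S(t) for t = 2..5 is
    S(1) times the Kaplan-Meier maintenance estimate among remitters, with
    relapses recorded at an annual visit processed before end-of-follow-up
    censorings at the same visit, while missing-record censorings leave the
    risk set half a cycle early (their information ends at the previous
    assessment). An arm with no remitters yields the zero schedule.
    """
    from lifelines import KaplanMeierFitter

    n = len(cohort_arm)
    if n == 0:
        raise ConfigurationError("empty arm")
    histories = [h for h in (classify_history(r) for r in cohort_arm) if h is not None]
    if not histories:
        return RemissionSchedule(np.zeros(FOLLOWUP_YEARS))
    p12 = len(histories) / n
    times = np.array([h.km_duration for h in histories])
    events = np.array([h.event for h in histories])
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    maint = np.array([float(kmf.predict(t)) for t in range(2, FOLLOWUP_YEARS + 1)])
    S = p12 * np.concatenate([[1.0], maint])
    S = np.minimum.accumulate(S)  # guard tiny numerical non-monotonicity
    return RemissionSchedule(S)


def extrapolate(schedule: RemissionSchedule, cap_years: int = 10) -> RemissionSchedule:
    """Extend a 5-year schedule to the remission cap.

    The annual retention beyond year 5 is the geometric mean rate observed
    between years 1 and 5, r = (S(5)/S(1))^(1/4); S(t) = S(5) * r^(t-5) for
    5 < t <= cap, and 0 thereafter. A schedule already absorbed (S(5) = 0) is
    returned unchanged apart from zero-padding to the cap.
    """
    S = schedule.S[:FOLLOWUP_YEARS]
    if len(S) < FOLLOWUP_YEARS:
        raise ConfigurationError("schedule must cover years 1-5 before extrapolation")
    ext = np.zeros(cap_years)
    ext[:FOLLOWUP_YEARS] = S
    if S[-1] <= 0 or S[0] <= 0:
        return RemissionSchedule(ext, cap_years=cap_years, extrapolation_rate=0.0)
    r = (S[-1] / S[0]) ** (1.0 / (FOLLOWUP_YEARS - 1))
    for t in range(FOLLOWUP_YEARS + 1, cap_years + 1):
        ext[t - 1] = S[-1] * r ** (t - FOLLOWUP_YEARS)
    return RemissionSchedule(ext, cap_years=cap_years, extrapolation_rate=float(r))
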