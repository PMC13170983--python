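"""Unit costing and Kaplan–Meier sampling-average cost estimation.

The KM sampling-average estimator handles right-censored cost data by taking,
for each follow-up year, the mean annual cost among participants still under
observation in that year; the Markov model then applies these means to the
modelled proportion surviving. Under the assumption that costs of observed
participants are representative of survivors, this avoids the downward bias of
summing censored participant totals. With no censoring it reduces exactly to
the complete-case mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel

from .config import (
    ARMS,
    COST_CATEGORIES,
    FOLLOWUP_YEARS,
    YEAR1_ONLY_PHASES,
    Cohort,
    ConfigurationError,
    EstimationError,
    ParticipantRecord,
)

__all__ = [
    "UnitCosts",
    "AnnualCostEstimate",
    "cost_intervention",
    "cost_hospitalisation",
    "summarize_annual_costs",
    "km_sampling_average",
    "remission_cost_saving_fraction",
]


class UnitCosts(BaseModel):
    """Unit prices (GBP, 2020/21 unless relabelled).

    The packaged defaults (see :mod:`remicea.defaults`) are calibration
    choices: the sources behind them publish schedules, not single prices, and
    the values shipped here are tuned so the costed base case reproduces the
    intervention cost components of the reference analysis.
    """

    setup_per_participant: float = 68.0
    sachet: float = 1.50
    practitioner_minute: float = 0.74
    visit_default_minutes: float = 25.0
    contact_costs: dict[str, float] = {
        "GP": 39.0, "nurse": 10.0, "healthcare assistant": 6.0,
        "other": 80.0, "secondary care": 252.0,
    }
    hospital_episode_base: dict[str, float] = {"elective": 3800.0, "non_elective": 2800.0}
    excess_bed_day: float = 343.0
    trim_point: dict[str, float] = {"elective": 9.0, "non_elective": 7.0}
    price_year: str = "2020/21"

    def __init__(self, **data):
        # raise ConfigurationError directly (unwrapped by pydantic)
        super().__init__(**data)
        self._check()

    def _check(self):
        vals = [self.setup_per_participant, self.sachet, self.practitioner_minute,
                self.visit_default_minutes, self.excess_bed_day,
                *self.contact_costs.values(), *self.hospital_episode_base.values(),
                *self.trim_point.values()]
        if any((not np.isfinite(v)) or v < 0 for v in vals):
            raise ConfigurationError("all unit costs must be finite and >= 0")


@dataclass
class AnnualCostEstimate:
    """KM sampling-average mean annual healthcare cost for one arm-year."""

    arm: str
    year: int
    per_category_mean: dict
    n_observed: int

    @property
    def total_mean(self) -> float:
        return float(sum(self.per_category_mean.values()))


def cost_intervention(record: ParticipantRecord, uc: UnitCosts) -> dict[int, float]:
    """Intervention delivery cost per follow-up year for one participant.

    Year-1 cost carries the flat per-participant set-up share; every year adds
    sachets * sachet price + visit minutes * practitioner cost per minute.
    Control-arm participants always cost 0.
    """
    if record.arm != "intervention":
        return {y: 0.0 for y in range(1, FOLLOWUP_YEARS + 1)}
    for d in (record.sachets, record.visits):
        if any(v < 0 for v in d.values()):
            raise ConfigurationError(f"negative resource count for participant {record.id}")
    out = {}
    for y in range(1, FOLLOWUP_YEARS + 1):
        sach = sum(v for (ph, yy), v in record.sachets.items() if yy == y)
        visits = sum(v for (ph, yy), v in record.visits.items() if yy == y)
        cost = sach * uc.sachet + visits * uc.visit_default_minutes * uc.practitioner_minute
        if y == 1:
            cost += uc.setup_per_participant
        out[y] = cost
    return out


def mean_intervention_cost_by_year(cohort: Cohort, uc: UnitCosts) -> np.ndarray:
    """Mean intervention cost per year among intervention participants observed in that year."""
    recs = list(cohort.arm("intervention"))
    if not recs:
        raise EstimationError("no intervention-arm participants")
    out = np.zeros(FOLLOWUP_YEARS)
    for y in range(1, FOLLOWUP_YEARS + 1):
        obs = [r for r in recs if y in r.observed_years()]
        if not obs:
            raise EstimationError(f"no intervention participants observed in year {y}")
        out[y - 1] = float(np.mean([cost_intervention(r, uc)[y] for r in obs]))
    return out


def cost_hospitalisation(length_of_stay: float, category: str, uc: UnitCosts) -> float:
    """Episode cost: tariff base plus excess bed-days beyond the trim point."""
    if length_of_stay < 0:
        raise ConfigurationError(f"length_of_stay must be >= 0; got {length_of_stay}")
    try:
        base = uc.hospital_episode_base[category]
        trim = uc.trim_point[category]
    except KeyError:
        raise KeyError(
            f"unknown admission category {category!r}; known: {sorted(uc.hospital_episode_base)}"
        ) from None
    return base + max(0.0, length_of_stay - trim) * uc.excess_bed_day


def summarize_annual_costs(cohort: Cohort) -> pd.DataFrame:
    """Per-arm per-category mean and SD over participant-years with observations.

    The ``total`` row is the participant-year total (exact sum of categories);
    SD is NaN when only one participant-year is observed.
    """
    costs = cohort.costs_frame()
    rows = []
    for arm in ARMS:
        sub = costs[costs.arm == arm]
        if sub.empty:
            raise EstimationError(f"no observed participant-years in arm {arm!r}")
        for cat in [*COST_CATEGORIES, "total"]:
            v = sub[cat].values
            rows.append({
                "arm": arm, "category": cat, "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan,
                "n_participant_years": len(v),
            })
    return pd.DataFrame(rows)


def km_sampling_average(
    cohort: Cohort, arm: str, year: int, in_remission: bool | None = None
) -> AnnualCostEstimate:
    """Mean annual cost among participants under observation in (arm, year).

    ``in_remission`` restricts to participants in (True) or out of (False)
    remission during that year, for remission-status-based costing.
    """
    recs = [r for r in cohort.arm(arm) if year in r.annual_costs]
    if in_remission is not None:
        recs = [r for r in recs if r.in_remission(year) == in_remission]
    if not recs:
        raise EstimationError(
            f"no cost observations for arm={arm!r}, year={year}"
            + ("" if in_remission is None else f", in_remission={in_remission}")
        )
    means = {
        cat: float(np.mean([r.annual_costs[year].get(cat, 0.0) for r in recs]))
        for cat in COST_CATEGORIES
    }
    return AnnualCostEstimate(arm=arm, year=year, per_category_mean=means, n_observed=len(recs))


def km_cost_table(cohort: Cohort) -> pd.DataFrame:
    """KM sampling-average total mean cost for every arm-year, tidy format."""
    rows = []
    for arm in ARMS:
        for y in range(1, FOLLOWUP_YEARS + 1):
            est = km_sampling_average(cohort, arm, y)
            rows.append({"arm": arm, "year": y, "total_mean": est.total_mean,
                         "n_observed": est.n_observed, **est.per_category_mean})
    return pd.DataFrame(rows)


def remission_cost_saving_fraction(cohort: Cohort, years=range(2, FOLLOWUP_YEARS + 1)) -> float:
    """Average proportional cost-saving for remission vs non-remission, years 2-5.

    s = mean over years of (1 - mean_cost_remission / mean_cost_nonremission),
    pooled over both arms, clipped to [0, 1]. Used to extrapolate healthcare
    costs beyond the follow-up period.
    """
    ratios = []
    for y in years:
        rem = [
            sum(r.annual_costs[y].values())
            for r in cohort
            if y in r.annual_costs and r.in_remission(y)
        ]
        non = [
            sum(r.annual_costs[y].values())
            for r in cohort
            if y in r.annual_costs and not r.in_remission(y)
        ]
        if not rem or not non:
            continue  # a bootstrap resample may lack remitters in a year
        non_mean = np.mean(non)
        if non_mean <= 0:
            raise EstimationError(f"non-remission mean cost is zero in year {y}")
        ratios.append(np.mean(rem) / non_mean)
    if not ratios:
        return 0.0
    return float(np.clip(1.0 - np.mean(ratios), 0.0, 1.0))
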