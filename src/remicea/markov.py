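"""Three-state Markov cohort model: type 2 diabetes, remission, death.

A closed cohort enters at a fixed age; each annual cycle the alive cohort is
split into remission and diabetes according to the arm-level remission
schedule (applied to survivors), each alive state experiences its own
mortality, and discounted costs, life-years and QALYs accrue on cycle-start
occupancy (no half-cycle correction). Healthcare costs in years 1-5 are the
arm-year mean costs applied to the alive proportion; beyond year 5 both arms
cost the control arm's year-5 non-remission mean, with a proportional saving
while in remission. Intervention costs apply to the intervention arm in years
1-5 only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import (
    ARMS,
    FOLLOWUP_YEARS,
    ConfigurationError,
    ModelConfig,
    MortalityInputs,
)
from .remission import RemissionSchedule
from .utility import UtilityInputs, state_utilities

__all__ = [
    "HealthcareCostInputs",
    "ModelInputs",
    "CohortTrace",
    "CEResult",
    "discount_factor",
    "run_cohort",
    "summarize",
    "net_monetary_benefit",
]


def discount_factor(year: int, rate: float = 0.035, first_year_undiscounted: bool = True) -> float:
    """Discount factor for an annual cycle; year 1 is undiscounted by default."""
    if year < 1:
        raise ConfigurationError(f"cycle index must be >= 1; got {year}")
    expo = year - 1 if first_year_undiscounted else year
    return 1.0 / (1.0 + rate) ** expo


@dataclass
class HealthcareCostInputs:
    """Mean annual healthcare costs feeding the model.

    ``arm_year_mean[arm]`` holds the KM sampling-average total means for years
    1-5. In ``arm_by_remission`` mode, years 1-5 instead use the remission /
    non-remission means within each arm. ``c5_nonremission_control`` and
    ``remission_saving_fraction`` parameterize the beyond-year-5 rule.
    """

    arm_year_mean: dict[str, np.ndarray]
    c5_nonremission_control: float
    remission_saving_fraction: float
    mode: str = "arm"
    rem_mean: Optional[dict[str, np.ndarray]] = None
    nonrem_mean: Optional[dict[str, np.ndarray]] = None

    def __post_init__(self):
        if self.mode not in ("arm", "arm_by_remission"):
            raise ConfigurationError(f"unknown costing mode {self.mode!r}")
        if self.mode == "arm_by_remission" and (self.rem_mean is None or self.nonrem_mean is None):
            raise ConfigurationError("arm_by_remission mode needs rem_mean and nonrem_mean")
        if not (0.0 <= self.remission_saving_fraction <= 1.0):
            raise ConfigurationError("remission_saving_fraction must be in [0, 1]")

    def annual_cost(self, arm: str, year: int, alive: float, in_remission: float) -> float:
        """Healthcare cost accrued in one cycle given occupancies."""
        if year <= FOLLOWUP_YEARS:
            if self.mode == "arm":
                return float(self.arm_year_mean[arm][year - 1]) * alive
            return (
                float(self.nonrem_mean[arm][year - 1]) * (alive - in_remission)
                + float(self.rem_mean[arm][year - 1]) * in_remission
            )
        c = self.c5_nonremission_control
        return c * (alive - self.remission_saving_fraction * in_remission)


@dataclass
class ModelInputs:
    """Everything the engine needs besides the run configuration."""

    schedules: dict[str, RemissionSchedule]   # extrapolated, per arm
    mortality: MortalityInputs
    utility: UtilityInputs
    costs: HealthcareCostInputs
    intervention_cost_year: np.ndarray        # mean GBP per year 1-5, intervention arm


@dataclass
class CohortTrace:
    """Per-cycle accounting for one arm."""

    arm: str
    years: np.ndarray
    occupancy: pd.DataFrame     # columns diabetes, remission, dead
    healthcare_cost: np.ndarray  # undiscounted GBP per cycle
    intervention_cost: np.ndarray
    qaly: np.ndarray             # undiscounted utility-weighted occupancy
    life_years: np.ndarray
    remission_years: np.ndarray
    discount: np.ndarray

    def total(self, name: str, discounted: bool = True, through_year: int | None = None) -> float:
        v = getattr(self, name)
        w = self.discount if discounted else np.ones_like(self.discount)
        if through_year is not None:
            v, w = v[:through_year], w[:through_year]
        return float(np.sum(v * w))


def run_cohort(config: ModelConfig, arm: str, inputs: ModelInputs) -> CohortTrace:
    """Run the cohort model for one arm over the configured horizon."""
    schedule = inputs.schedules[arm]
    horizon = FOLLOWUP_YEARS if config.horizon == "five_year" else None
    if horizon is not None and len(schedule.S) < horizon:
        raise ConfigurationError(
            f"schedule covers {len(schedule.S)} years but horizon needs {horizon}"
        )
    q = inputs.mortality.blended(config.fraction_women)
    q_ages = q.index.values.astype(float)

    # precompute per-cycle age-indexed vectors up to the maximum possible run
    max_cycles = (
        horizon if horizon is not None else int(config.max_age - config.start_age) + 1
    )
    ages = config.start_age + np.arange(max_cycles)
    age_idx = np.clip(np.searchsorted(q_ages, ages, side="right") - 1, 0, len(q_ages) - 1)
    q_d = q.q_diabetes.values[age_idx]
    q_r = q.q_nondiabetes.values[age_idx]
    norm = inputs.utility.norm_array(ages, config.fraction_women)
    u_diab = norm * (1.0 - inputs.utility.relative_decrement_diabetes)
    u_rem = norm * (1.0 - inputs.utility.relative_decrement_remission)
    expo = np.arange(max_cycles) if config.first_year_undiscounted else np.arange(1, max_cycles + 1)
    disc = 1.0 / (1.0 + config.discount_rate) ** expo

    cols = {k: [] for k in ("diabetes", "remission", "dead", "healthcare_cost",
                            "intervention_cost", "qaly", "life_years",
                            "remission_years")}
    alive = 1.0
    n = 0
    for k in range(max_cycles):
        t = k + 1
        if horizon is None and alive < config.alive_tolerance:
            break
        rem = schedule.proportion(t) * alive
        diab = alive - rem
        hc = inputs.costs.annual_cost(arm, t, alive, rem)
        iv = (
            float(inputs.intervention_cost_year[t - 1]) * alive
            if (arm == "intervention" and t <= FOLLOWUP_YEARS)
            else 0.0
        )
        cols["diabetes"].append(diab)
        cols["remission"].append(rem)
        cols["dead"].append(1.0 - alive)
        cols["healthcare_cost"].append(hc)
        cols["intervention_cost"].append(iv)
        cols["qaly"].append(diab * u_diab[k] + rem * u_rem[k])
        cols["life_years"].append(alive)
        cols["remission_years"].append(rem)
        n += 1
        alive = alive - diab * q_d[k] - rem * q_r[k]

    arrs = {k: np.asarray(v) for k, v in cols.items()}
    return CohortTrace(
        arm=arm,
        years=np.arange(1, n + 1),
        occupancy=pd.DataFrame({k: arrs[k] for k in ("diabetes", "remission", "dead")}),
        healthcare_cost=arrs["healthcare_cost"],
        intervention_cost=arrs["intervention_cost"],
        qaly=arrs["qaly"],
        life_years=arrs["life_years"],
        remission_years=arrs["remission_years"],
        discount=disc[:n],
    )


@dataclass
class CEResult:
    """Arm totals, incrementals and the cost-effectiveness verdict.

    Costs and QALYs are discounted; life-years and remission-years are
    reported undiscounted (with discounted remission-years alongside).
    Incrementals are intervention minus control.
    """

    per_arm: pd.DataFrame
    incremental: pd.Series
    icer: float | str
    horizon: str

    @property
    def dominant(self) -> bool:
        return self.icer == "dominant"


def summarize(trace_intervention: CohortTrace, trace_control: CohortTrace, horizon: str = "lifetime") -> CEResult:
    """Combine two arm traces into totals, incrementals and an ICER/dominance verdict."""
    cols = {}
    for tr in (trace_intervention, trace_control):
        hc5 = tr.total("healthcare_cost", through_year=FOLLOWUP_YEARS)
        iv5 = tr.total("intervention_cost", through_year=FOLLOWUP_YEARS)
        cols[tr.arm] = {
            "intervention_cost_5yr": iv5,
            "healthcare_cost_5yr": hc5,
            "total_cost_5yr": hc5 + iv5,
            "qaly_5yr": tr.total("qaly", through_year=FOLLOWUP_YEARS),
            "healthcare_cost": tr.total("healthcare_cost"),
            "intervention_cost": tr.total("intervention_cost"),
            "total_cost": tr.total("healthcare_cost") + tr.total("intervention_cost"),
            "qaly": tr.total("qaly"),
            "life_years": tr.total("life_years", discounted=False),
            "remission_years": tr.total("remission_years", discounted=False),
            "remission_years_discounted": tr.total("remission_years"),
        }
    per_arm = pd.DataFrame(cols)
    inc = per_arm["intervention"] - per_arm["control"]
    dc, dq = inc["total_cost"], inc["qaly"]
    if dc < 0 and dq > 0:
        icer: float | str = "dominant"
    elif dq == 0:
        icer = np.inf if dc > 0 else (-np.inf if dc < 0 else 0.0)
    else:
        icer = dc / dq
    return CEResult(per_arm=per_arm, incremental=inc, icer=icer, horizon=horizon)


def net_monetary_benefit(result: CEResult, threshold: float) -> float:
    """NMB = threshold * incremental QALYs - incremental cost (GBP)."""
    if threshold < 0:
        raise ConfigurationError("willingness-to-pay threshold must be >= 0")
    return float(threshold * result.incremental["qaly"] - result.incremental["total_cost"])


def run_base_case(config: ModelConfig, inputs: ModelInputs) -> CEResult:
    """Run both arms and summarize."""
    ti = run_cohort(config, "intervention", inputs)
    tc = run_cohort(config, "control", inputs)
    return summarize(ti, tc, horizon=config.horizon)
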