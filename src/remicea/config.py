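"""Domain types and configuration objects.

Currency is GBP at 2020/21 prices throughout. Cycle length is one year;
"year 1" is the first follow-up year after entry (entry at age 54 by default).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

#: Healthcare cost categories, in reporting order.
COST_CATEGORIES = ["primary_care", "other", "secondary_care", "hospital", "medicines"]

#: Intervention delivery phases. Total diet replacement and food reintroduction
#: occur in year 1 only; weight-loss management and rescue run through year 5.
PHASES = ["total_diet_replacement", "food_reintroduction", "weight_loss_management", "rescue"]
YEAR1_ONLY_PHASES = ("total_diet_replacement", "food_reintroduction")

ARMS = ("intervention", "control")

#: EQ-5D-3L UK value-set index range.
EQ5D_MIN, EQ5D_MAX = -0.594, 1.0

FOLLOWUP_YEARS = 5


class Arm(str, enum.Enum):
    intervention = "intervention"
    control = "control"


class ConfigurationError(ValueError):
    """A model or generator input is out of range or inconsistent."""


class EstimationError(RuntimeError):
    """An estimator was asked for a quantity its data cannot support."""


@dataclass
class ParticipantRecord:
    """One synthetic trial participant.

    ``annual_costs`` maps year (1-5) -> {category: GBP}; entries exist only for
    observed years (``year <= censor_year`` when censored). ``sachets`` and
    ``visits`` map (phase, year) -> count, intervention arm only. ``eq5d`` is a
    list of (visit_year, utility_index, in_remission_at_visit); visit year 0 is
    the pre-intervention baseline. ``annual_status`` holds the raw annual
    remission assessment strings for years 2-5 ("in_remission", "relapsed",
    "missing") as recorded, before any censoring-rule classification.
    """

    id: str
    arm: str
    sex: str
    age_at_entry: float
    extension_participant: bool
    remission_12m: bool
    relapse_year: Optional[int] = None
    censor_year: Optional[int] = None
    annual_costs: dict = field(default_factory=dict)
    sachets: dict = field(default_factory=dict)
    visits: dict = field(default_factory=dict)
    eq5d: list = field(default_factory=list)
    annual_status: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.relapse_year is not None and self.relapse_year <= 1:
            raise ConfigurationError(
                f"relapse_year must exceed 1 (remission is assessed at 12 months); got {self.relapse_year}"
            )
        for _, u, _ in self.eq5d:
            if not (EQ5D_MIN - 1e-9 <= u <= EQ5D_MAX + 1e-9):
                raise ConfigurationError(f"EQ-5D index {u} outside [{EQ5D_MIN}, {EQ5D_MAX}]")
        for d in (self.sachets, self.visits):
            for k, v in d.items():
                if v < 0:
                    raise ConfigurationError(f"negative resource count {v} at {k}")

    def in_remission(self, year: int) -> bool:
        """True remission state in follow-up year ``year`` (1-based).

        Remission is anchored at the 12-month assessment and is absorbing once
        relapsed: a participant is in remission in year y iff they remitted at
        12 months and have not relapsed by year y.
        """
        if year < 1 or not self.remission_12m:
            return False
        return self.relapse_year is None or year < self.relapse_year

    def observed_years(self) -> range:
        last = self.censor_year if self.censor_year is not None else FOLLOWUP_YEARS
        return range(1, last + 1)


class Cohort:
    """A collection of participant records with tidy-table accessors."""

    def __init__(self, records: list[ParticipantRecord]):
        self.records = list(records)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other):
        return isinstance(other, Cohort) and self.records == other.records

    def arm(self, arm: str) -> "Cohort":
        return Cohort([r for r in self.records if r.arm == arm])

    def participants_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "id": r.id, "arm": r.arm, "sex": r.sex, "age_at_entry": r.age_at_entry,
                "extension_participant": r.extension_participant,
                "remission_12m": r.remission_12m,
                "relapse_year": r.relapse_year, "censor_year": r.censor_year,
            }
            for y in range(2, FOLLOWUP_YEARS + 1):
                row[f"status_year{y}"] = r.annual_status.get(y, "")
            for ph in PHASES:
                for y in range(1, FOLLOWUP_YEARS + 1):
                    if ph in YEAR1_ONLY_PHASES and y > 1:
                        continue
                    row[f"sachets_{ph}_y{y}"] = r.sachets.get((ph, y), np.nan)
                    row[f"visits_{ph}_y{y}"] = r.visits.get((ph, y), np.nan)
            rows.append(row)
        return pd.DataFrame(rows)

    def costs_frame(self) -> pd.DataFrame:
        """Long table: one row per observed participant-year, category columns."""
        rows = []
        for r in self.records:
            for y, cats in sorted(r.annual_costs.items()):
                row = {"id": r.id, "arm": r.arm, "year": y,
                       "in_remission": r.in_remission(y)}
                row.update({c: cats.get(c, 0.0) for c in COST_CATEGORIES})
                row["total"] = sum(row[c] for c in COST_CATEGORIES)
                rows.append(row)
        return pd.DataFrame(rows)

    def eq5d_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            for year, u, rem in r.eq5d:
                rows.append({"id": r.id, "arm": r.arm, "visit_year": year,
                             "utility": u, "in_remission": rem,
                             "sex": r.sex, "age_at_entry": r.age_at_entry})
        return pd.DataFrame(rows)


class GeneratorParams(BaseModel):
    """Synthetic-cohort generator settings.

    Defaults (see :mod:`remicea.defaults`) emulate the trial structure: two arms
    of 149 participants entering at age 54 (59% women); 12-month remission in
    46% of the intervention arm (5% control) declining to ~9.7% at year 5;
    right-skewed annual healthcare costs with a per-participant frailty shared
    across years and categories; intervention resource use (formula-diet sachets
    and practitioner visits) by phase and year; and an EQ-5D-3L panel with a
    true remission utility increment.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    n_per_arm: int = 149
    start_age: float = 54.0
    fraction_women: float = 0.59
    remission_12m_prob: dict[str, float]
    annual_retention: dict[str, tuple[float, float, float, float]]
    annual_dropout_hazard: float = 0.02
    assessment_miss_prob: float = 0.01
    extension_prob: float = 0.58
    dropout_remission_log_hr: float = 0.0  # informative-censoring knob; 0 = independent

    cost_means: pd.DataFrame  # index (arm, year), columns COST_CATEGORIES, GBP
    cost_sds: pd.DataFrame    # same shape, marginal SDs
    remission_cost_reduction: float = 0.45  # proportional saving while in remission
    cost_frailty_sd: float = 1.05           # SD of per-participant mean-1 gamma frailty

    intervention_resource: pd.DataFrame  # index (phase, year): sachets/visits mean & sd

    utility_effect_remission: float = 0.037
    utility_baseline_mean: float = 0.70
    utility_noise_sd: float = 0.10
    subject_effect_sd: float = 0.12

    calibrate: bool = False
    seed: int = 0

    def __init__(self, **data):
        # raise ConfigurationError directly (unwrapped by pydantic)
        super().__init__(**data)
        self._check()

    def _check(self):
        props = {
            "fraction_women": self.fraction_women,
            "annual_dropout_hazard": self.annual_dropout_hazard,
            "assessment_miss_prob": self.assessment_miss_prob,
            "extension_prob": self.extension_prob,
            "remission_cost_reduction": self.remission_cost_reduction,
        }
        props.update({f"remission_12m_prob[{a}]": p for a, p in self.remission_12m_prob.items()})
        for arm, rr in self.annual_retention.items():
            props.update({f"annual_retention[{arm}][{i}]": p for i, p in enumerate(rr)})
        for name, p in props.items():
            if not np.isfinite(p) or not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name} must be a proportion in [0, 1]; got {p}")
        if self.n_per_arm < 2:
            raise ConfigurationError(f"n_per_arm must be >= 2; got {self.n_per_arm}")
        if (self.cost_means.values < 0).any() or not np.isfinite(self.cost_means.values).all():
            raise ConfigurationError("cost_means must be finite and non-negative")
        if (self.cost_sds.values < 0).any() or not np.isfinite(self.cost_sds.values).all():
            raise ConfigurationError("cost_sds must be finite and non-negative")
        for f in ("cost_frailty_sd", "utility_noise_sd", "subject_effect_sd"):
            if getattr(self, f) < 0:
                raise ConfigurationError(f"{f} must be >= 0")
        if not (EQ5D_MIN <= self.utility_baseline_mean <= EQ5D_MAX):
            raise ConfigurationError("utility_baseline_mean outside the EQ-5D index range")

    def arm_schedule(self, arm: str) -> np.ndarray:
        """Implied true arm-level remission proportions S(1..5)."""
        s = [self.remission_12m_prob[arm]]
        for rho in self.annual_retention[arm]:
            s.append(s[-1] * rho)
        return np.array(s)


class ModelConfig(BaseModel):
    """Markov cohort model settings."""

    start_age: float = 54.0
    fraction_women: float = 0.59
    horizon: str = "lifetime"  # "five_year" | "lifetime"
    discount_rate: float = 0.035
    remission_cap_years: int = 10
    max_age: float = 110.0
    alive_tolerance: float = 1e-6
    first_year_undiscounted: bool = True

    def __init__(self, **data):
        # raise ConfigurationError directly (unwrapped by pydantic)
        super().__init__(**data)
        self._check()

    def _check(self):
        if self.discount_rate < 0:
            raise ConfigurationError("discount_rate must be >= 0")
        if self.horizon not in ("five_year", "lifetime"):
            raise ConfigurationError(f"horizon must be 'five_year' or 'lifetime'; got {self.horizon!r}")
        if not (0.0 <= self.fraction_women <= 1.0):
            raise ConfigurationError("fraction_women must be in [0, 1]")


@dataclass
class MortalityInputs:
    """Annual death probabilities by age and sex, by diabetes status.

    ``table`` has columns (age, sex, q_diabetes, q_nondiabetes); the
    non-diabetes rates apply while in remission. ``rel_se`` parameterizes the
    beta uncertainty used by the PSA (method-of-moments, SE = rel_se * rate).
    """

    table: pd.DataFrame
    rel_se: float = 0.10

    def __post_init__(self):
        t = self.table
        need = {"age", "sex", "q_diabetes", "q_nondiabetes"}
        if not need.issubset(t.columns):
            raise ConfigurationError(f"mortality table needs columns {sorted(need)}")
        q = t[["q_diabetes", "q_nondiabetes"]].values
        if ((q < 0) | (q > 1)).any():
            raise ConfigurationError("mortality probabilities must lie in [0, 1]")
        if (t["q_nondiabetes"] > t["q_diabetes"] + 1e-12).any():
            raise ConfigurationError("q_nondiabetes must not exceed q_diabetes at any age")

    def blended(self, fraction_women: float) -> pd.DataFrame:
        """Sex-blended rates indexed by integer age (cohort-level approximation)."""
        w = self.table[self.table.sex == "F"].set_index("age").sort_index()
        m = self.table[self.table.sex == "M"].set_index("age").sort_index()
        out = pd.DataFrame({
            "q_diabetes": fraction_women * w.q_diabetes + (1 - fraction_women) * m.q_diabetes,
            "q_nondiabetes": fraction_women * w.q_nondiabetes + (1 - fraction_women) * m.q_nondiabetes,
        })
        return out

    def scaled(self, f_diabetes: float, f_nondiabetes: float) -> "MortalityInputs":
        t = self.table.copy()
        t["q_diabetes"] = np.clip(t["q_diabetes"] * f_diabetes, 0.0, 1.0)
        t["q_nondiabetes"] = np.minimum(
            np.clip(t["q_nondiabetes"] * f_nondiabetes, 0.0, 1.0), t["q_diabetes"]
        )
        return MortalityInputs(table=t, rel_se=self.rel_se)
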