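"""Estimation pipeline: turn a participant-level cohort into Markov model inputs.

This is the analysis path the PSA bootstraps: Kaplan–Meier remission schedules
per arm (extrapolated to the remission cap), KM sampling-average healthcare
costs per arm-year, the remission cost-saving fraction, mean intervention
delivery costs, and the GEE utility effect mapped to state-utility decrements.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .config import ARMS, FOLLOWUP_YEARS, Cohort, ModelConfig, MortalityInputs
from .costing import (
    UnitCosts,
    km_sampling_average,
    mean_intervention_cost_by_year,
    remission_cost_saving_fraction,
)
from .markov import HealthcareCostInputs, ModelInputs
from .remission import extrapolate, km_remission
from .utility import UtilityEffect, derive_inputs, fit_gee_utility

__all__ = ["estimate_inputs"]


def estimate_inputs(
    cohort: Cohort,
    unit_costs: UnitCosts,
    mortality: MortalityInputs,
    norms: pd.DataFrame,
    config: ModelConfig | None = None,
    utility_effect: UtilityEffect | None = None,
    costing_mode: str = "arm",
) -> ModelInputs:
    """Estimate every model input from participant-level data.

    ``utility_effect`` can be supplied to skip the GEE fit (the PSA draws the
    effect rather than refitting per bootstrap resample).
    """
    config = config or ModelConfig()

    schedules = {
        arm: extrapolate(km_remission(cohort.arm(arm)), cap_years=config.remission_cap_years)
        for arm in ARMS
    }

    arm_year = {
        arm: np.array(
            [km_sampling_average(cohort, arm, y).total_mean for y in range(1, FOLLOWUP_YEARS + 1)]
        )
        for arm in ARMS
    }
    s = remission_cost_saving_fraction(cohort)

    def _status_mean(arm, y, in_remission):
        try:
            return km_sampling_average(cohort, arm, y, in_remission=in_remission).total_mean
        except Exception:  # a (re)sample may lack remitters in a cell
            base = km_sampling_average(cohort, arm, y).total_mean
            return base * (1.0 - s) if in_remission else base

    rem_mean = nonrem_mean = None
    if costing_mode == "arm_by_remission":
        rem_mean = {
            arm: np.array([_status_mean(arm, y, True) for y in range(1, FOLLOWUP_YEARS + 1)])
            for arm in ARMS
        }
        nonrem_mean = {
            arm: np.array([_status_mean(arm, y, False) for y in range(1, FOLLOWUP_YEARS + 1)])
            for arm in ARMS
        }
    c5nr = _status_mean("control", FOLLOWUP_YEARS, False)

    costs = HealthcareCostInputs(
        arm_year_mean=arm_year,
        c5_nonremission_control=float(c5nr),
        remission_saving_fraction=s,
        mode=costing_mode,
        rem_mean=rem_mean,
        nonrem_mean=nonrem_mean,
    )

    if utility_effect is None:
        utility_effect = fit_gee_utility(cohort.eq5d_frame())
    baseline_pred = (
        utility_effect.intercept
        if utility_effect.intercept is not None
        else float(np.mean([u for r in cohort for (_, u, rem) in r.eq5d if not rem]))
    )
    utility = derive_inputs(
        norms, utility_effect, baseline_pred, config.start_age, config.fraction_women
    )

    return ModelInputs(
        schedules=schedules,
        mortality=mortality,
        utility=utility,
        costs=costs,
        intervention_cost_year=mean_intervention_cost_by_year(cohort, unit_costs),
    )
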