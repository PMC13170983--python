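"""Scenario analyses: structured modifications of the base-case inputs.

Each scenario limits a channel through which remission produces benefit:
the mortality advantage (scaled between the non-diabetes and diabetes rates),
the utility advantage, the amount of remission itself, the costing basis
(arm-only vs arm-and-remission-status), or the time horizon. The base case is
exactly recovered when every scale is 1, no override is set and costing is by
arm. All scenarios in a batch share a seed policy so differences between rows
are attributable to the modification, not to sampling.
"""

from __future__ import annotations

from dataclasses import replace as dc_replace

import numpy as np
import pandas as pd
from pydantic import BaseModel

from .config import Cohort, ConfigurationError, ModelConfig, MortalityInputs
from .costing import UnitCosts
from .markov import ModelInputs
from .psa import PSAResult, run_psa
from .utility import derive_inputs

__all__ = ["ScenarioSpec", "apply_scenario", "run_all", "DEFAULT_SCENARIOS"]


class ScenarioSpec(BaseModel):
    """One scenario row. Scales interpolate between no effect (0) and base case (1)."""

    name: str
    mortality_effect_scale: float = 1.0
    qol_effect_scale: float = 1.0
    remission_scale: float = 1.0
    horizon_override: str | None = None
    costing_mode: str = "arm"

    def __init__(self, **data):
        # raise ConfigurationError directly (unwrapped by pydantic)
        super().__init__(**data)
        self._check()

    def _check(self):
        for f in ("mortality_effect_scale", "qol_effect_scale", "remission_scale"):
            v = getattr(self, f)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{f} must be in [0, 1]; got {v}")
        if self.horizon_override not in (None, "five_year"):
            raise ConfigurationError("horizon_override must be None or 'five_year'")
        if self.costing_mode not in ("arm", "arm_by_remission"):
            raise ConfigurationError(f"unknown costing_mode {self.costing_mode!r}")

    @property
    def is_base_case(self) -> bool:
        return (
            self.mortality_effect_scale == 1.0
            and self.qol_effect_scale == 1.0
            and self.remission_scale == 1.0
            and self.horizon_override is None
            and self.costing_mode == "arm"
        )


#: The reference scenario set (base case first).
DEFAULT_SCENARIOS = [
    ScenarioSpec(name="base_case"),
    ScenarioSpec(name="mortality_effect_50pct", mortality_effect_scale=0.5),
    ScenarioSpec(name="mortality_effect_zero", mortality_effect_scale=0.0),
    ScenarioSpec(name="qol_effect_50pct", qol_effect_scale=0.5),
    ScenarioSpec(name="qol_effect_zero", qol_effect_scale=0.0),
    ScenarioSpec(name="remission_based_costing", costing_mode="arm_by_remission"),
    ScenarioSpec(name="five_year_horizon", horizon_override="five_year"),
    ScenarioSpec(
        name="remission_50pct_reduction",
        remission_scale=0.5,
        costing_mode="arm_by_remission",
    ),
]


def apply_scenario(spec: ScenarioSpec, inputs: ModelInputs, config: ModelConfig):
    """Return modified ``(inputs, config)`` for one scenario.

    The mortality scale interpolates the remission-state rate between the
    diabetes rate (scale 0) and the non-diabetes rate (scale 1). The QoL scale
    multiplies the remission utility increment before the relative decrements
    are rebuilt. The remission scale multiplies the whole schedule, including
    years 1 and 2 and the extrapolated tail. Costing mode is selected upstream
    during estimation (the estimated remission/non-remission means must exist);
    apply_scenario validates the combination.
    """
    if spec.costing_mode == "arm_by_remission" and inputs.costs.rem_mean is None:
        raise ConfigurationError(
            "scenario requires remission-status cost estimates; "
            "re-estimate inputs with costing_mode='arm_by_remission'"
        )

    new_inputs = inputs
    if spec.remission_scale != 1.0:
        new_inputs = dc_replace(
            new_inputs,
            schedules={a: s.scaled(spec.remission_scale) for a, s in inputs.schedules.items()},
        )

    if spec.mortality_effect_scale != 1.0:
        t = inputs.mortality.table.copy()
        m = spec.mortality_effect_scale
        t["q_nondiabetes"] = t["q_diabetes"] + m * (t["q_nondiabetes"] - t["q_diabetes"])
        new_inputs = dc_replace(
            new_inputs, mortality=MortalityInputs(table=t, rel_se=inputs.mortality.rel_se)
        )

    if spec.qol_effect_scale != 1.0:
        u = inputs.utility
        eff = dc_replace(u.remission_effect, estimate=u.remission_effect.estimate * spec.qol_effect_scale)
        new_inputs = dc_replace(
            new_inputs,
            utility=derive_inputs(
                u.norms, eff, u.baseline_predicted_utility,
                config.start_age, config.fraction_women,
            ),
        )

    mode = "arm_by_remission" if spec.costing_mode == "arm_by_remission" else "arm"
    if mode != inputs.costs.mode:
        new_inputs = dc_replace(new_inputs, costs=dc_replace(inputs.costs, mode=mode))

    new_config = config
    if spec.horizon_override is not None:
        new_config = config.model_copy(update={"horizon": spec.horizon_override})
    return new_inputs, new_config


def run_all(
    specs: list[ScenarioSpec],
    cohort: Cohort,
    unit_costs: UnitCosts,
    mortality: MortalityInputs,
    norms: pd.DataFrame,
    config: ModelConfig | None = None,
    n_iter: int = 1000,
    seed: int = 0,
    threshold: float = 20_000.0,
) -> tuple[pd.DataFrame, dict[str, PSAResult]]:
    """One PSA per scenario with a shared seed; summary table plus full results.

    The table reports incremental cost and QALYs (point estimates with 2.5/97.5
    bootstrap percentiles), the probability of cost-saving and the probability
    of cost-effectiveness at ``threshold``.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate scenario names in {names}")
    config = config or ModelConfig()

    rows = []
    results = {}
    for spec in specs:
        mode = "arm_by_remission" if spec.costing_mode == "arm_by_remission" else "arm"
        res = run_psa(
            cohort, unit_costs, mortality, norms, config,
            n_iter=n_iter, seed=seed, costing_mode=mode,
            transform=lambda inp, cfg, _s=spec: apply_scenario(_s, inp, cfg),
        )
        results[spec.name] = res
        pct = res.percentile_intervals
        rows.append({
            "scenario": spec.name,
            "incremental_cost": res.point.incremental["total_cost"],
            "incremental_cost_lo": pct.loc[0.025, "delta_cost"],
            "incremental_cost_hi": pct.loc[0.975, "delta_cost"],
            "incremental_qaly": res.point.incremental["qaly"],
            "incremental_qaly_lo": pct.loc[0.025, "delta_qaly"],
            "incremental_qaly_hi": pct.loc[0.975, "delta_qaly"],
            "p_cost_saving": res.p_cost_saving,
            "p_cost_effective": res.prob_cost_effective(threshold),
        })
    return pd.DataFrame(rows), results
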