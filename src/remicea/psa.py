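"""Probabilistic sensitivity analysis.

Uncertainty propagation combines (i) a nonparametric bootstrap of the
participant-level data, stratified by arm with the original arm sizes, which
covers remission maintenance, healthcare resource use and intervention
resource use; (ii) a Monte-Carlo normal draw of the remission utility effect
around the fitted GEE coefficient; and (iii) beta draws (method of moments)
of the mortality rates by diabetes status. Each iteration re-runs the Markov
model; outputs are percentile intervals, the probability of cost-saving, and
the cost-effectiveness acceptability curve (CEAC).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import ARMS, Cohort, ConfigurationError, ModelConfig, MortalityInputs
from .costing import UnitCosts
from .markov import CEResult, ModelInputs, run_base_case
from .pipeline import estimate_inputs
from .utility import UtilityEffect, fit_gee_utility

__all__ = ["PSAResult", "bootstrap_iteration", "run_psa", "ceac"]

DEFAULT_THRESHOLDS = np.arange(0, 50_001, 1_000)


@dataclass
class PSAResult:
    """Draws and summaries from one PSA run."""

    draws: pd.DataFrame            # one row per iteration
    point: CEResult                # deterministic run on the original cohort
    ceac: pd.DataFrame             # (threshold, probability)
    percentile_intervals: pd.DataFrame  # 2.5% / 97.5% per output column
    p_cost_saving: float
    n_redrawn: int
    seed: int

    def prob_cost_effective(self, threshold: float) -> float:
        row = self.ceac[np.isclose(self.ceac.threshold, threshold)]
        if row.empty:
            return float(
                np.mean(threshold * self.draws.delta_qaly - self.draws.delta_cost > 0)
            )
        return float(row.probability.iloc[0])


def bootstrap_iteration(cohort: Cohort, rng: np.random.Generator) -> Cohort:
    """Resample participants with replacement within each arm (original sizes)."""
    records = []
    for arm in ARMS:
        recs = cohort.arm(arm).records
        if not recs:
            raise ConfigurationError(f"cannot bootstrap an empty arm: {arm}")
        idx = rng.integers(0, len(recs), size=len(recs))
        records.extend(recs[i] for i in idx)
    return Cohort(records)


def _beta_factor(rng: np.random.Generator, mean: float, rel_se: float) -> float:
    """Multiplicative mortality uncertainty: a beta draw around a reference rate."""
    if rel_se <= 0 or mean <= 0:
        return 1.0
    var = (rel_se * mean) ** 2
    nu = mean * (1 - mean) / var - 1.0
    if nu <= 0:  # variance too large for a beta; fall back to the mean
        return 1.0
    a, b = mean * nu, (1 - mean) * nu
    return float(rng.beta(a, b) / mean)


def ceac(draws: pd.DataFrame, thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Probability of positive net monetary benefit per willingness-to-pay threshold."""
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ConfigurationError("threshold grid must be non-empty")
    if len(draws) == 0:
        raise ConfigurationError("need at least one PSA draw")
    nmb = thresholds[:, None] * draws.delta_qaly.values[None, :] - draws.delta_cost.values[None, :]
    return pd.DataFrame({"threshold": thresholds, "probability": (nmb > 0).mean(axis=1)})


def run_psa(
    cohort: Cohort,
    unit_costs: UnitCosts,
    mortality: MortalityInputs,
    norms: pd.DataFrame,
    config: ModelConfig | None = None,
    n_iter: int = 1000,
    seed: int = 0,
    thresholds=DEFAULT_THRESHOLDS,
    costing_mode: str = "arm",
    transform=None,
    utility_effect: UtilityEffect | None = None,
) -> PSAResult:
    """Bootstrap + Monte-Carlo PSA. ``(seed, n_iter)`` fully determine the result.

    ``transform``, if given, is a callable ``(inputs, config) -> (inputs, config)``
    applied to every iteration's estimated inputs (and to the point estimate);
    scenario analyses are expressed this way.
    """
    if n_iter < 2:
        raise ConfigurationError("n_iter must be >= 2")
    config = config or ModelConfig()
    rng = np.random.default_rng(seed)

    if utility_effect is None:
        utility_effect = fit_gee_utility(cohort.eq5d_frame())

    def _run(inp: ModelInputs, cfg: ModelConfig) -> CEResult:
        if transform is not None:
            inp, cfg = transform(inp, cfg)
        return run_base_case(cfg, inp)

    point_inputs = estimate_inputs(
        cohort, unit_costs, mortality, norms, config,
        utility_effect=utility_effect, costing_mode=costing_mode,
    )
    point = _run(point_inputs, config)

    # reference rates for the beta mortality draws: blended rate at entry age + 10
    blended = mortality.blended(config.fraction_women)
    ref_age = min(int(config.start_age) + 10, int(blended.index.max()))
    q_ref = blended.loc[ref_age]

    rows = []
    n_redrawn = 0
    it = 0
    while it < n_iter:
        boot = bootstrap_iteration(cohort, rng)
        eff = replace(utility_effect, estimate=float(rng.normal(utility_effect.estimate, utility_effect.se)))
        f_d = _beta_factor(rng, q_ref.q_diabetes, mortality.rel_se)
        f_r = _beta_factor(rng, q_ref.q_nondiabetes, mortality.rel_se)
        inputs = estimate_inputs(
            boot, unit_costs, mortality.scaled(f_d, f_r), norms, config,
            utility_effect=eff, costing_mode=costing_mode,
        )
        res = _run(inputs, config)
        vals = {
            "iteration": it,
            "cost_intervention_arm": res.per_arm.loc["total_cost", "intervention"],
            "cost_control_arm": res.per_arm.loc["total_cost", "control"],
            "qaly_intervention_arm": res.per_arm.loc["qaly", "intervention"],
            "qaly_control_arm": res.per_arm.loc["qaly", "control"],
            "delta_cost": res.incremental["total_cost"],
            "delta_qaly": res.incremental["qaly"],
            "delta_life_years": res.incremental["life_years"],
        }
        if not all(np.isfinite(v) for v in vals.values()):
            n_redrawn += 1
            continue
        rows.append(vals)
        it += 1

    draws = pd.DataFrame(rows)
    curve = ceac(draws, thresholds)
    qcols = [c for c in draws.columns if c != "iteration"]
    # empirical percentiles: with two draws the interval is exactly (min, max)
    pct = pd.DataFrame(
        {c: [np.quantile(draws[c], 0.025, method="lower"),
             np.quantile(draws[c], 0.975, method="higher")] for c in qcols},
        index=[0.025, 0.975],
    )
    return PSAResult(
        draws=draws,
        point=point,
        ceac=curve,
        percentile_intervals=pct,
        p_cost_saving=float((draws.delta_cost < 0).mean()),
        n_redrawn=n_redrawn,
        seed=seed,
    )


def plot_ceac(result: PSAResult, path=None):
    """CEAC plot (probability cost-effective vs willingness-to-pay threshold)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(result.ceac.threshold, result.ceac.probability)
    ax.set_xlabel("Willingness to pay (GBP per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1.02)
    ax.grid(alpha=0.3)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
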