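"""Health-related quality of life: repeated-measures remission effect and
Markov state utilities.

The remission effect on the EQ-5D-3L index is estimated with a marginal linear
model (GEE, exchangeable working correlation, robust standard errors) over the
repeated annual utility observations. State utilities for the cohort model are
UK population norms by age with relative decrements for the diabetes and
remission states; the decrements are derived from the regression's predicted
utilities at the baseline age/sex relative to the age/sex-matched norm, so the
absolute remission benefit shrinks proportionally as norms decline with age.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigurationError, EstimationError

__all__ = ["UtilityEffect", "UtilityInputs", "fit_gee_utility", "state_utilities", "derive_inputs"]

log = logging.getLogger(__name__)


@dataclass
class UtilityEffect:
    """Fitted marginal remission effect on the EQ-5D index.

    ``intercept`` is the marginal non-remission mean utility (the model's
    prediction at baseline with no covariates), used to derive the diabetes
    decrement against the population norm.
    """

    estimate: float
    se: float
    p_value: float
    n_subjects: int
    n_observations: int
    intercept: float | None = None


@dataclass
class UtilityInputs:
    """State-utility construction inputs for the Markov model.

    ``norms`` has columns (age_lo, age_hi, sex, utility). Decrements are
    proportions of the norm lost in each alive state.
    """

    norms: pd.DataFrame
    baseline_predicted_utility: float
    remission_effect: UtilityEffect
    relative_decrement_diabetes: float
    relative_decrement_remission: float

    def __post_init__(self):
        for d in (self.relative_decrement_diabetes, self.relative_decrement_remission):
            if not (0.0 <= d <= 1.0):
                raise ConfigurationError(f"relative decrement {d} outside [0, 1]")
        if self.remission_effect.se <= 0:
            raise ConfigurationError("remission effect SE must be > 0")

    def norm_at(self, age: float, fraction_women: float) -> float:
        """Sex-mix-weighted population norm, clamping beyond the last age band."""
        out = 0.0
        for sex, w in (("F", fraction_women), ("M", 1.0 - fraction_women)):
            t = self.norms[self.norms.sex == sex].sort_values("age_lo")
            if t.empty:
                raise ConfigurationError(f"norm table lacks sex {sex!r}")
            row = t[(t.age_lo <= age) & (age <= t.age_hi)]
            if row.empty:
                if age > t.age_hi.max():
                    log.warning("age %.0f beyond norm table; clamping to last band", age)
                    row = t.iloc[[-1]]
                else:
                    row = t.iloc[[0]]
            out += w * float(row.utility.iloc[0])
        return out

    def norm_array(self, ages: np.ndarray, fraction_women: float) -> np.ndarray:
        """Vectorized sex-mix-weighted norms; ages beyond the table clamp to the
        last band (the scalar path logs the clamp warning)."""
        ages = np.asarray(ages, dtype=float)
        out = np.zeros_like(ages)
        for sex, w in (("F", fraction_women), ("M", 1.0 - fraction_women)):
            t = self.norms[self.norms.sex == sex].sort_values("age_lo")
            idx = np.clip(np.searchsorted(t.age_lo.values, ages, side="right") - 1, 0, len(t) - 1)
            out += w * t.utility.values[idx]
        return out


def fit_gee_utility(panel: pd.DataFrame, covariates: list[str] | None = None) -> UtilityEffect:
    """Marginal regression of utility on remission status.

    ``panel`` is long-format with columns (id, utility, in_remission) and
    optional baseline covariates. Exchangeable within-subject correlation,
    robust (sandwich) standard errors.
    """
    import statsmodels.api as sm

    need = {"id", "utility", "in_remission"}
    if not need.issubset(panel.columns):
        raise ConfigurationError(f"EQ-5D panel needs columns {sorted(need)}")
    if panel.in_remission.nunique() < 2:
        raise EstimationError("remission status does not vary within the panel")
    if panel.id.nunique() < 2:
        raise EstimationError("need at least two subjects")
    if panel.utility.nunique() == 1:
        # degenerate panel with constant utility: the effect is exactly zero
        return UtilityEffect(0.0, 0.0, 1.0, int(panel.id.nunique()), len(panel),
                             intercept=float(panel.utility.iloc[0]))

    X = pd.DataFrame({"remission": panel.in_remission.astype(float)})
    for c in covariates or []:
        X[c] = pd.to_numeric(panel[c], errors="coerce")
    X = sm.add_constant(X)
    model = sm.GEE(
        panel.utility.values, X.values, groups=panel.id.values,
        cov_struct=sm.cov_struct.Exchangeable(),
    )
    res = model.fit()
    i = list(X.columns).index("remission")
    return UtilityEffect(
        estimate=float(res.params[i]),
        se=float(res.bse[i]),
        p_value=float(res.pvalues[i]),
        n_subjects=int(panel.id.nunique()),
        n_observations=len(panel),
        intercept=float(res.params[list(X.columns).index("const")]),
    )


def derive_inputs(
    norms: pd.DataFrame,
    effect: UtilityEffect,
    baseline_predicted_utility: float,
    baseline_age: float,
    fraction_women: float,
) -> UtilityInputs:
    """Build state-utility inputs from a fitted remission effect.

    The diabetes decrement compares the regression's predicted non-remission
    utility at baseline age/sex with the population norm; the remission
    decrement adds the remission effect to that prediction. A positive effect
    therefore yields a strictly smaller remission decrement.
    """
    tmp = UtilityInputs(norms, baseline_predicted_utility, effect, 0.0, 0.0)
    norm0 = tmp.norm_at(baseline_age, fraction_women)
    if norm0 <= 0:
        raise ConfigurationError("population norm at baseline must be positive")
    dec_d = max(0.0, 1.0 - baseline_predicted_utility / norm0)
    dec_r = max(0.0, 1.0 - (baseline_predicted_utility + effect.estimate) / norm0)
    return UtilityInputs(norms, baseline_predicted_utility, effect, dec_d, dec_r)


def state_utilities(inputs: UtilityInputs, age: float, fraction_women: float) -> dict[str, float]:
    """Per-state utility at a given attained age. Death has utility 0."""
    norm = inputs.norm_at(age, fraction_women)
    return {
        "diabetes": norm * (1.0 - inputs.relative_decrement_diabetes),
        "remission": norm * (1.0 - inputs.relative_decrement_remission),
        "dead": 0.0,
    }
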