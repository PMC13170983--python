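"""Synthetic participant-level cohort generator.

Generates two-arm trial data with the statistical structure the downstream
analysis assumes: 12-month remission with annual relapse thereafter (absorbing),
right-censoring from dropout, right-skewed annual healthcare costs by category
with a per-participant frailty shared across years (chronically high-cost
participants stay high-cost, which is what makes bootstrap uncertainty on
multi-year cost sums realistic), intervention resource use by phase and year,
and a repeated-measures EQ-5D-3L panel with a true remission utility increment.

Two sampling modes:

* stochastic (``calibrate=False``): plain i.i.d. draws; used for
  parameter-recovery simulation studies.
* calibrated (``calibrate=True``): after drawing, sample moments are rescaled
  to the configured cell means (remission counts, cost-cell means, intervention
  resource means, fitted utility effect). This emulates analysing a *specific*
  observed dataset whose summary statistics are known, so single-cohort
  analyses anchor at the configured values while individual-level spread — and
  hence bootstrap uncertainty — is preserved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    ARMS,
    COST_CATEGORIES,
    EQ5D_MAX,
    EQ5D_MIN,
    FOLLOWUP_YEARS,
    PHASES,
    YEAR1_ONLY_PHASES,
    Cohort,
    ConfigurationError,
    GeneratorParams,
    ParticipantRecord,
)

__all__ = ["generate_cohort", "write_cohort", "read_cohort"]


def _gamma_mean_sd(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Gamma draw parameterized by mean and SD; degenerate at the mean if sd=0."""
    if mean <= 0:
        return np.zeros(size) if size is not None else 0.0
    if sd <= 0:
        return np.full(size, mean) if size is not None else mean
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size=size)


def _allocate_counts(n: int, fractions: np.ndarray) -> np.ndarray:
    """Integer counts summing to n, proportional to ``fractions`` (largest-remainder)."""
    raw = fractions * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def _draw_relapse_years(rng, n_rem: int, retention: np.ndarray, calibrate: bool):
    """Relapse year (2-5, or 0 = maintained through year 5) for each remitter."""
    if n_rem == 0:
        return np.zeros(0, dtype=int)
    if not calibrate:
        relapse = np.zeros(n_rem, dtype=int)
        alive = np.ones(n_rem, dtype=bool)
        for i, rho in enumerate(retention):  # years 2..5
            year = i + 2
            fail = alive & (rng.random(n_rem) > rho)
            relapse[fail] = year
            alive &= ~fail
        return relapse
    # exact expected counts maintaining at each year, randomized assignment
    surv = np.cumprod(retention)  # P(maintain through year 2..5) given 12m remission
    n_maint = np.rint(surv * n_rem).astype(int)
    n_maint = np.minimum.accumulate(n_maint)  # monotone non-increasing
    relapse = np.zeros(n_rem, dtype=int)
    order = rng.permutation(n_rem)
    lo = n_maint[-1]  # first lo participants (in permuted order) never relapse
    for i in range(len(retention) - 1, -1, -1):
        hi = n_maint[i - 1] if i > 0 else n_rem
        relapse[order[lo:hi]] = i + 2
        lo = hi
    return relapse


def _conditional_sd(mean: float, sd: float, frailty_var: float) -> float:
    """SD of the cost draw conditional on a mean-1 frailty with variance phi^2.

    Chosen so the marginal SD matches ``sd``:
    Var(X) = (1 + phi^2) * (s^2 + m^2) - m^2  for X | f ~ Gamma(f*m, f*s).
    Returns 0 when the frailty alone already exceeds the target marginal SD.
    """
    s2 = (sd**2 + mean**2) / (1.0 + frailty_var) - mean**2
    return np.sqrt(s2) if s2 > 0 else 0.0


def generate_cohort(params: GeneratorParams) -> Cohort:
    """Generate ``2 * n_per_arm`` participant records. Identical seed => identical cohort."""
    rng = np.random.default_rng(params.seed)
    records: list[ParticipantRecord] = []
    frailty_var = params.cost_frailty_sd**2

    for arm in ARMS:
        n = params.n_per_arm
        prefix = "I" if arm == "intervention" else "C"
        schedule = params.arm_schedule(arm)
        retention = np.asarray(params.annual_retention[arm])

        # -- sex ------------------------------------------------------------
        if params.calibrate:
            n_f = int(round(params.fraction_women * n))
            sexes = np.array(["F"] * n_f + ["M"] * (n - n_f))
            rng.shuffle(sexes)
        else:
            sexes = np.where(rng.random(n) < params.fraction_women, "F", "M")

        # -- 12-month remission and relapse year ----------------------------
        p12 = params.remission_12m_prob[arm]
        if params.calibrate:
            n_rem = int(round(p12 * n))
            rem12 = np.zeros(n, dtype=bool)
            rem12[rng.permutation(n)[:n_rem]] = True
        else:
            rem12 = rng.random(n) < p12
            n_rem = int(rem12.sum())
        relapse_all = np.zeros(n, dtype=int)
        relapse_all[rem12] = _draw_relapse_years(rng, n_rem, retention, params.calibrate)

        def in_rem_at(y):
            return rem12 & ((relapse_all == 0) | (y < relapse_all))

        # -- dropout (annual discrete hazard; censor_year = last observed year)
        censor = np.zeros(n, dtype=int)  # 0 = complete follow-up
        h0 = params.annual_dropout_hazard
        at_risk = np.ones(n, dtype=bool)
        for y in range(1, FOLLOWUP_YEARS):
            h = np.minimum(1.0, h0 * np.exp(params.dropout_remission_log_hr * in_rem_at(y)))
            drop = at_risk & (rng.random(n) < h)
            censor[drop] = y
            at_risk &= ~drop

        # -- extension participation (intervention arm only) -----------------
        if arm == "intervention":
            ext = rng.random(n) < params.extension_prob
        else:
            ext = np.zeros(n, dtype=bool)

        # -- per-participant cost frailty ------------------------------------
        if frailty_var > 0:
            frailty = rng.gamma(1.0 / frailty_var, frailty_var, size=n)
        else:
            frailty = np.ones(n)

        subject_effects = rng.normal(0.0, params.subject_effect_sd, size=n)

        # -- healthcare cost draws, vectorized per (year, category) -----------
        # conditional-on-frailty gamma: X | f ~ Gamma(mean f*m_cell, sd f*s_cell)
        # where s_cell scales with the cell mean, so the gamma shape is shared
        # across remission cells and only the scale varies per participant.
        delta = params.remission_cost_reduction
        observed = censor == 0
        obs_year = np.where(observed, FOLLOWUP_YEARS, censor)
        cost_draws = np.zeros((n, FOLLOWUP_YEARS, len(COST_CATEGORIES)))
        for y in range(1, FOLLOWUP_YEARS + 1):
            r_y = schedule[y - 1]
            rem_y = in_rem_at(y)
            for ci, cat in enumerate(COST_CATEGORIES):
                m = params.cost_means.loc[(arm, y), cat]
                if m <= 0:
                    continue
                sd = params.cost_sds.loc[(arm, y), cat]
                u = m / (1.0 - delta * r_y) if delta * r_y < 1 else m
                cell_mean = np.where(rem_y, u * (1.0 - delta), u)
                s_base = _conditional_sd(m, sd, frailty_var)
                if s_base <= 0:
                    cost_draws[:, y - 1, ci] = frailty * cell_mean
                else:
                    shape = (m / s_base) ** 2
                    scale = frailty * (s_base**2 / m) * (cell_mean / m)
                    cost_draws[:, y - 1, ci] = rng.gamma(shape, scale)

        # -- intervention resource draws, vectorized per (phase, year) -------
        resource_draws = {}
        if arm == "intervention":
            for (ph, y), row in params.intervention_resource.iterrows():
                resource_draws[(ph, y)] = (
                    _gamma_mean_sd(rng, row.sachets_mean, row.sachets_sd, size=n),
                    _gamma_mean_sd(rng, row.visits_mean, row.visits_sd, size=n),
                )

        # -- EQ-5D noise draws ------------------------------------------------
        eq_noise = rng.normal(0.0, params.utility_noise_sd, size=(n, FOLLOWUP_YEARS + 1))
        # -- annual-assessment miss draws (remitters, years 2-5) --------------
        miss_draws = rng.random((n, FOLLOWUP_YEARS - 1)) < params.assessment_miss_prob

        for i in range(n):
            rec = ParticipantRecord(
                id=f"{prefix}{i + 1:03d}",
                arm=arm,
                sex=str(sexes[i]),
                age_at_entry=params.start_age,
                extension_participant=bool(ext[i]),
                remission_12m=bool(rem12[i]),
                relapse_year=int(relapse_all[i]) if relapse_all[i] else None,
                censor_year=int(censor[i]) if censor[i] else None,
            )

            # annual remission assessment records (years 2-5), remitters only
            if rec.remission_12m:
                for y in range(2, FOLLOWUP_YEARS + 1):
                    if (rec.censor_year is not None and y > rec.censor_year) or miss_draws[i, y - 2]:
                        rec.annual_status[y] = "missing"
                    else:
                        rec.annual_status[y] = (
                            "in_remission" if rec.in_remission(y) else "relapsed"
                        )

            # healthcare costs for observed years
            for y in rec.observed_years():
                rec.annual_costs[y] = {
                    cat: float(cost_draws[i, y - 1, ci])
                    for ci, cat in enumerate(COST_CATEGORIES)
                }

            # intervention resource use for observed years
            if arm == "intervention":
                last = obs_year[i]
                for (ph, y), (sach, vis) in resource_draws.items():
                    if y <= last:
                        rec.sachets[(ph, y)] = float(sach[i])
                        rec.visits[(ph, y)] = float(vis[i])

            # EQ-5D panel: baseline and years 1-2 for everyone under observation,
            # years 3-5 only in the intervention-arm extension group
            visit_years = [0, 1, 2]
            if arm == "intervention" and rec.extension_participant:
                visit_years += [3, 4, 5]
            for y in visit_years:
                if y > 0 and rec.censor_year is not None and y > rec.censor_year:
                    continue
                in_rem = rec.in_remission(y)
                u = (
                    params.utility_baseline_mean
                    + subject_effects[i]
                    + params.utility_effect_remission * in_rem
                    + eq_noise[i, y]
                )
                rec.eq5d.append((y, float(np.clip(u, EQ5D_MIN, EQ5D_MAX)), bool(in_rem)))

            records.append(rec)

    cohort = Cohort(records)
    if params.calibrate:
        _calibrate_costs(cohort, params)
        _calibrate_resource(cohort, params)
        _calibrate_utility_effect(cohort, params)
    return cohort


# ---------------------------------------------------------------------------
# calibrated-mode moment matching
# ---------------------------------------------------------------------------

def _calibrate_costs(cohort: Cohort, params: GeneratorParams) -> None:
    """Rescale cost draws so each (arm, year, remission, category) cell mean equals
    its target, and each (arm, year, category) mean equals the configured mean exactly."""
    delta = params.remission_cost_reduction
    for arm in ARMS:
        for y in range(1, FOLLOWUP_YEARS + 1):
            obs = [r for r in cohort.arm(arm) if y in r.annual_costs]
            if not obs:
                continue
            rem = [r for r in obs if r.in_remission(y)]
            non = [r for r in obs if not r.in_remission(y)]
            for cat in COST_CATEGORIES:
                m = float(params.cost_means.loc[(arm, y), cat])
                if m <= 0:
                    for r in obs:
                        r.annual_costs[y][cat] = 0.0
                    continue
                # cell targets chosen so the weighted arm-year mean is exactly m
                u = m * len(obs) / (len(non) + (1.0 - delta) * len(rem))
                for group, target in ((non, u), (rem, u * (1.0 - delta))):
                    if not group:
                        continue
                    cur = np.mean([r.annual_costs[y][cat] for r in group])
                    if cur > 0:
                        f = target / cur
                        for r in group:
                            r.annual_costs[y][cat] *= f
                    else:
                        for r in group:
                            r.annual_costs[y][cat] = target


def _calibrate_resource(cohort: Cohort, params: GeneratorParams) -> None:
    for (ph, y), row in params.intervention_resource.iterrows():
        for attr, target in (("sachets", row.sachets_mean), ("visits", row.visits_mean)):
            vals = [getattr(r, attr) for r in cohort.arm("intervention") if (ph, y) in getattr(r, attr)]
            holders = [d for d in vals]
            if not holders:
                continue
            cur = np.mean([d[(ph, y)] for d in holders])
            if cur > 0 and target > 0:
                f = target / cur
                for d in holders:
                    d[(ph, y)] *= f
            elif target == 0:
                for d in holders:
                    d[(ph, y)] = 0.0


def _calibrate_utility_effect(cohort: Cohort, params: GeneratorParams) -> None:
    """Shift remission-visit utilities so the fitted GEE effect equals the target."""
    from .utility import fit_gee_utility

    panel = cohort.eq5d_frame()
    if panel.empty or panel.in_remission.nunique() < 2:
        return
    for _ in range(2):  # one shift is nearly exact for a linear model; iterate twice
        eff = fit_gee_utility(panel)
        shift = params.utility_effect_remission - eff.estimate
        if abs(shift) < 1e-10:
            break
        for r in cohort:
            r.eq5d = [
                (y, float(np.clip(u + shift * rem, EQ5D_MIN, EQ5D_MAX)), rem)
                for (y, u, rem) in r.eq5d
            ]
        panel = cohort.eq5d_frame()


# ---------------------------------------------------------------------------
# round-trip I/O (comma-separated text tables)
# ---------------------------------------------------------------------------

_PARTICIPANT_FILE = "participants.csv"
_COSTS_FILE = "annual_costs.csv"
_EQ5D_FILE = "eq5d_panel.csv"


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as three delimited tables under directory ``path``.

    Unobserved years are *absent* from the long cost table (explicit missing,
    never zero); optional scalar fields use empty strings for missing.
    """
    import os

    os.makedirs(path, exist_ok=True)
    part = cohort.participants_frame()
    if part.empty:
        from .config import PHASES, YEAR1_ONLY_PHASES

        cols = ["id", "arm", "sex", "age_at_entry", "extension_participant",
                "remission_12m", "relapse_year", "censor_year"]
        cols += [f"status_year{y}" for y in range(2, FOLLOWUP_YEARS + 1)]
        for ph in PHASES:
            for y in range(1, FOLLOWUP_YEARS + 1):
                if ph in YEAR1_ONLY_PHASES and y > 1:
                    continue
                cols += [f"sachets_{ph}_y{y}", f"visits_{ph}_y{y}"]
        part = pd.DataFrame(columns=cols)
    # %.17g guarantees float64 round-trip through text
    part.to_csv(os.path.join(path, _PARTICIPANT_FILE), index=False, float_format="%.17g")
    costs = cohort.costs_frame()
    if costs.empty:
        costs = pd.DataFrame(columns=["id", "arm", "year", "in_remission", *COST_CATEGORIES, "total"])
    costs.drop(columns=["total"]).to_csv(
        os.path.join(path, _COSTS_FILE), index=False, float_format="%.17g"
    )
    eq = cohort.eq5d_frame()
    if eq.empty:
        eq = pd.DataFrame(columns=["id", "arm", "visit_year", "utility", "in_remission", "sex", "age_at_entry"])
    eq.to_csv(os.path.join(path, _EQ5D_FILE), index=False, float_format="%.17g")


def read_cohort(path) -> Cohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    import os

    def _err(fname, exc):
        raise ConfigurationError(f"malformed cohort file {fname}: {exc}") from exc

    fname = os.path.join(path, _PARTICIPANT_FILE)
    try:
        part = pd.read_csv(fname, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001
        _err(fname, exc)
    costs = pd.read_csv(os.path.join(path, _COSTS_FILE), float_precision="round_trip")
    eq = pd.read_csv(os.path.join(path, _EQ5D_FILE), float_precision="round_trip")

    records = []
    cost_rows = {k: g for k, g in costs.groupby("id")} if len(costs) else {}
    eq_rows = {k: g for k, g in eq.groupby("id")} if len(eq) else {}
    for li, row in part.iterrows():
        try:
            rec = ParticipantRecord(
                id=row["id"],
                arm=row["arm"],
                sex=row["sex"],
                age_at_entry=float(row["age_at_entry"]),
                extension_participant=bool(row["extension_participant"]),
                remission_12m=bool(row["remission_12m"]),
                relapse_year=None if pd.isna(row["relapse_year"]) else int(row["relapse_year"]),
                censor_year=None if pd.isna(row["censor_year"]) else int(row["censor_year"]),
            )
        except (KeyError, ValueError) as exc:
            raise ConfigurationError(
                f"malformed participant row at line {li + 2} of {_PARTICIPANT_FILE}: {exc}"
            ) from exc
        for y in range(2, FOLLOWUP_YEARS + 1):
            s = row.get(f"status_year{y}")
            if isinstance(s, str) and s:
                rec.annual_status[y] = s
        for ph in PHASES:
            for y in range(1, FOLLOWUP_YEARS + 1):
                if ph in YEAR1_ONLY_PHASES and y > 1:
                    continue
                sv = row.get(f"sachets_{ph}_y{y}")
                vv = row.get(f"visits_{ph}_y{y}")
                if sv is not None and not pd.isna(sv):
                    rec.sachets[(ph, y)] = float(sv)
                if vv is not None and not pd.isna(vv):
                    rec.visits[(ph, y)] = float(vv)
        for _, c in cost_rows.get(rec.id, pd.DataFrame()).iterrows():
            rec.annual_costs[int(c["year"])] = {cat: float(c[cat]) for cat in COST_CATEGORIES}
        g = eq_rows.get(rec.id)
        if g is not None:
            for _, e in g.sort_values("visit_year").iterrows():
                rec.eq5d.append((int(e["visit_year"]), float(e["utility"]), bool(e["in_remission"])))
        records.append(rec)
    return Cohort(records)
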