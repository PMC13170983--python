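"""Three-state Markov cohort engine: discounting, accounting, invariants, oracle."""

import numpy as np
import pandas as pd
import pytest

from remicea import defaults
from remicea.config import ConfigurationError, ModelConfig, MortalityInputs
from remicea.markov import (
    CohortTrace,
    HealthcareCostInputs,
    ModelInputs,
    discount_factor,
    net_monetary_benefit,
    run_base_case,
    run_cohort,
    summarize,
)
from remicea.remission import RemissionSchedule, extrapolate
from remicea.utility import UtilityEffect, derive_inputs


def flat_mortality(q_d, q_nd, ages=range(54, 111)):
    rows = [{"age": a, "sex": s, "q_diabetes": q_d, "q_nondiabetes": q_nd}
            for a in ages for s in ("F", "M")]
    return MortalityInputs(table=pd.DataFrame(rows))


def make_inputs(S=(0.46, 0.36, 0.29, 0.21, 0.097), q_d=0.01, q_nd=0.006,
                hc=(1500.0,) * 5, iv=(1000.0, 200.0, 100.0, 100.0, 50.0),
                s=0.5, c5nr=1600.0, baseline=0.75, effect=0.037):
    sched = extrapolate(RemissionSchedule(np.array(S)))
    ctl = extrapolate(RemissionSchedule(np.array(S) * 0.1))
    utility = derive_inputs(defaults.utility_norms(),
                            UtilityEffect(effect, 0.015, 0.02, 0, 0),
                            baseline, 54.0, 0.59)
    costs = HealthcareCostInputs(
        arm_year_mean={"intervention": np.array(hc) * 0.8, "control": np.array(hc)},
        c5_nonremission_control=c5nr, remission_saving_fraction=s,
    )
    return ModelInputs(schedules={"intervention": sched, "control": ctl},
                       mortality=flat_mortality(q_d, q_nd), utility=utility,
                       costs=costs, intervention_cost_year=np.array(iv))


class TestDiscountFactor:
    @pytest.mark.parametrize("year, rate, expected", [
        (1, 0.035, 1.0),                 # first year undiscounted
        (2, 0.035, 1.0 / 1.035),
        (3, 0.035, 1.0 / 1.035**2),
        (7, 0.0, 1.0),                   # zero rate
    ])
    def test_values(self, year, rate, expected):
        assert discount_factor(year, rate) == pytest.approx(expected)

    def test_cycle_index_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            discount_factor(0)


class TestRunCohort:
    def test_occupancy_conserved_and_death_absorbing(self):
        inputs = make_inputs(q_d=0.03, q_nd=0.01)
        trace = run_cohort(ModelConfig(), "intervention", inputs)
        occ = trace.occupancy
        assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-12)
        assert (np.diff(occ.dead.values) >= -1e-15).all()

    def test_zero_mortality_remission_years_equal_schedule_sum(self):
        inputs = make_inputs(q_d=0.0, q_nd=0.0)
        cfg = ModelConfig(horizon="five_year")
        trace = run_cohort(cfg, "intervention", inputs)
        assert trace.total("remission_years", discounted=False) == pytest.approx(
            0.46 + 0.36 + 0.29 + 0.21 + 0.097)  # = 1.417

    def test_equal_mortality_and_utilities_make_arms_symmetric(self):
        inputs = make_inputs(q_d=0.01, q_nd=0.01, effect=0.0)
        # give both arms the same healthcare costs so only remission paths differ
        inputs.costs.arm_year_mean["intervention"] = inputs.costs.arm_year_mean["control"]
        res = run_base_case(ModelConfig(), inputs)
        assert res.incremental["life_years"] == pytest.approx(0.0, abs=1e-12)
        assert res.incremental["qaly"] == pytest.approx(0.0, abs=1e-10)

    def test_short_schedule_rejected_for_five_year_horizon(self):
        inputs = make_inputs()
        inputs.schedules["intervention"] = RemissionSchedule(np.array([0.4, 0.3]))
        with pytest.raises(ConfigurationError, match="horizon"):
            run_cohort(ModelConfig(horizon="five_year"), "intervention", inputs)

    def test_discounting_monotonicity(self):
        """Every discounted total weakly decreases as the rate rises."""
        inputs = make_inputs()
        totals = []
        for rate in (0.0, 0.035, 0.07):
            res = run_base_case(ModelConfig(discount_rate=rate), inputs)
            totals.append(res.per_arm.loc[["total_cost", "qaly"], "control"])
        for a, b in zip(totals, totals[1:]):
            assert (b <= a + 1e-12).all()

    def test_engine_matches_brute_force_loop_oracle(self):
        """Independent per-cycle loop reproduces the trace exactly on random inputs."""
        rng = np.random.default_rng(8)
        for trial in range(5):
            S = np.sort(rng.uniform(0.0, 0.6, 5))[::-1]
            q_d = rng.uniform(0.005, 0.05)
            q_nd = q_d * rng.uniform(0.3, 1.0)
            hc = rng.uniform(500, 3000, 5)
            s = rng.uniform(0, 1)
            c5 = rng.uniform(800, 3000)
            inputs = make_inputs(S=S, q_d=q_d, q_nd=q_nd, hc=hc, s=s, c5nr=c5)
            cfg = ModelConfig()
            trace = run_cohort(cfg, "control", inputs)
            sched = inputs.schedules["control"]

            # ---- brute force oracle ----
            alive, cost, qaly, ly = 1.0, 0.0, 0.0, 0.0
            t = 0
            while alive >= 1e-6 and 54 + t <= 110:
                t += 1
                age = 54 + t - 1
                rem = sched.proportion(t) * alive
                d = 1.0 / 1.035 ** (t - 1)
                u_d = inputs.utility.norm_at(age, 0.59) * (
                    1 - inputs.utility.relative_decrement_diabetes)
                u_r = inputs.utility.norm_at(age, 0.59) * (
                    1 - inputs.utility.relative_decrement_remission)
                if t <= 5:
                    c = hc[t - 1] * alive
                else:
                    c = c5 * (alive - s * rem)
                cost += c * d
                qaly += ((alive - rem) * u_d + rem * u_r) * d
                ly += alive
                alive -= (alive - rem) * q_d + rem * q_nd

            assert trace.total("healthcare_cost") == pytest.approx(cost, rel=1e-12)
            assert trace.total("qaly") == pytest.approx(qaly, rel=1e-12)
            assert trace.total("life_years", discounted=False) == pytest.approx(ly, rel=1e-12)


class TestSummarize:
    def _trace(self, arm, hc, iv, qaly, ly, rem):
        one = np.array([1.0])
        return CohortTrace(arm=arm, years=np.array([1]),
                           occupancy=pd.DataFrame({"diabetes": one, "remission": one * 0,
                                                   "dead": one * 0}),
                           healthcare_cost=np.array([hc]),
                           intervention_cost=np.array([iv]), qaly=np.array([qaly]),
                           life_years=np.array([ly]), remission_years=np.array([rem]),
                           discount=one)

    def test_printed_arm_totals_give_printed_incrementals(self):
        """Internal consistency of the report arithmetic with the reference totals."""
        ti = self._trace("intervention", 5837.0, 1691.0, 3.41, 23.57, 1.46)
        tc = self._trace("control", 7928.0, 0.0, 3.37, 23.48, 0.15)
        res = summarize(ti, tc)
        assert res.incremental["total_cost_5yr"] == pytest.approx(1691 + 5837 - 7928)  # -400
        assert res.incremental["total_cost_5yr"] == pytest.approx(-400.0)
        assert res.incremental["healthcare_cost_5yr"] == pytest.approx(-2091.0)
        assert res.icer == "dominant"

    def test_dominance_label(self):
        ti = self._trace("intervention", 1000.0, 0.0, 1.08, 1.0, 0.0)
        tc = self._trace("control", 1496.0, 0.0, 1.00, 1.0, 0.0)
        res = summarize(ti, tc)
        assert res.incremental["total_cost"] == pytest.approx(-496.0)
        assert res.incremental["qaly"] == pytest.approx(0.08)
        assert res.dominant

    def test_identical_arms_give_zero_incrementals(self):
        ti = self._trace("intervention", 1000.0, 0.0, 1.0, 1.0, 0.1)
        tc = self._trace("control", 1000.0, 0.0, 1.0, 1.0, 0.1)
        res = summarize(ti, tc)
        assert (res.incremental == 0.0).all()
        assert res.icer == 0.0

    def test_zero_qaly_gain_with_cost_difference_flags_infinite_icer(self):
        ti = self._trace("intervention", 1200.0, 0.0, 1.0, 1.0, 0.0)
        tc = self._trace("control", 1000.0, 0.0, 1.0, 1.0, 0.0)
        assert summarize(ti, tc).icer == np.inf

    def test_positive_icer_when_more_costly_and_more_effective(self):
        ti = self._trace("intervention", 1500.0, 0.0, 1.05, 1.0, 0.0)
        tc = self._trace("control", 1000.0, 0.0, 1.00, 1.0, 0.0)
        assert summarize(ti, tc).icer == pytest.approx(500.0 / 0.05)


class TestNetMonetaryBenefit:
    def _result(self, dc, dq):
        inc = pd.Series({"total_cost": dc, "qaly": dq})
        from remicea.markov import CEResult
        return CEResult(per_arm=pd.DataFrame(), incremental=inc, icer=0.0, horizon="lifetime")

    @pytest.mark.parametrize("dc, dq, wtp, expected", [
        (-496.0, 0.08, 20_000.0, 20_000 * 0.08 + 496),   # 2096
        (-496.0, 0.08, 0.0, 496.0),                       # threshold 0 -> -dC
        (0.0, 0.0, 30_000.0, 0.0),
    ])
    def test_values(self, dc, dq, wtp, expected):
        assert net_monetary_benefit(self._result(dc, dq), wtp) == pytest.approx(expected)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            net_monetary_benefit(self._result(0, 0), -1.0)


def test_mortality_inputs_validation():
    with pytest.raises(ConfigurationError, match="q_nondiabetes"):
        flat_mortality(q_d=0.01, q_nd=0.02)
    with pytest.raises(ConfigurationError):
        flat_mortality(q_d=1.5, q_nd=0.5)
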