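"""Unit costing and KM sampling-average cost estimation."""

import numpy as np
import pytest

from remicea import defaults
from remicea.config import COST_CATEGORIES, ConfigurationError, EstimationError
from remicea.costing import (
    cost_hospitalisation,
    cost_intervention,
    km_sampling_average,
    remission_cost_saving_fraction,
    summarize_annual_costs,
)

from conftest import cohort_of, make_record


@pytest.fixture(scope="module")
def uc():
    return defaults.unit_costs()


class TestCostIntervention:
    def test_control_arm_is_always_zero(self, uc):
        rec = make_record(arm="control", costs={1: 500.0})
        assert all(v == 0.0 for v in cost_intervention(rec, uc).values())

    def test_year_without_resource_use_costs_nothing_beyond_setup(self, uc):
        rec = make_record(
            arm="intervention",
            sachets={("weight_loss_management", 1): 100.0, ("weight_loss_management", 3): 0.0},
            visits={("weight_loss_management", 1): 4.0, ("weight_loss_management", 3): 0.0},
        )
        by_year = cost_intervention(rec, uc)
        assert by_year[3] == 0.0
        assert by_year[1] == pytest.approx(
            uc.setup_per_participant
            + 100.0 * uc.sachet
            + 4.0 * uc.visit_default_minutes * uc.practitioner_minute
        )

    def test_setup_cost_applies_to_year_one_only(self, uc):
        rec = make_record(arm="intervention")
        by_year = cost_intervention(rec, uc)
        assert by_year[1] == uc.setup_per_participant
        assert all(by_year[y] == 0.0 for y in range(2, 6))

    def test_negative_counts_rejected(self, uc):
        rec = make_record(arm="intervention")
        rec.sachets[("rescue", 2)] = -1.0
        with pytest.raises(ConfigurationError, match="negative"):
            cost_intervention(rec, uc)


class TestCostHospitalisation:
    @pytest.mark.parametrize(
        "los, base, trim, excess, expected",
        [
            (3.0, 2000.0, 5.0, 300.0, 2000.0),   # below trim point
            (8.0, 2000.0, 5.0, 300.0, 2900.0),   # 2000 + 3 x 300
            (5.0, 2000.0, 5.0, 300.0, 2000.0),   # exactly at trim point
        ],
    )
    def test_excess_bed_day_rule(self, los, base, trim, excess, expected, uc):
        custom = uc.model_copy(update={
            "hospital_episode_base": {"elective": base},
            "trim_point": {"elective": trim},
            "excess_bed_day": excess,
        })
        assert cost_hospitalisation(los, "elective", custom) == pytest.approx(expected)

    def test_unknown_category_lists_known_ones(self, uc):
        with pytest.raises(KeyError, match="elective"):
            cost_hospitalisation(3.0, "day_case", uc)

    def test_negative_stay_rejected(self, uc):
        with pytest.raises(ConfigurationError):
            cost_hospitalisation(-1.0, "elective", uc)


class TestSummarizeAnnualCosts:
    def test_total_equals_sum_of_categories(self):
        # the printed per-annum category means; totals must be their exact sum
        printed = {
            "control": {"primary_care": 428.0, "other": 44.0, "secondary_care": 347.0,
                        "hospital": 690.0, "medicines": 300.0},
            "intervention": {"primary_care": 357.0, "other": 50.0, "secondary_care": 288.0,
                             "hospital": 412.0, "medicines": 222.0},
        }
        records = [
            make_record(id=f"{arm[0]}{i}", arm=arm, costs={1: printed[arm], 2: printed[arm]})
            for arm in ("control", "intervention") for i in range(3)
        ]
        table = summarize_annual_costs(cohort_of(*records)).set_index(["arm", "category"])
        assert table.loc[("control", "total"), "mean"] == pytest.approx(1809.0)
        assert table.loc[("intervention", "total"), "mean"] == pytest.approx(1329.0)
        for arm in ("control", "intervention"):
            cat_sum = sum(table.loc[(arm, c), "mean"] for c in COST_CATEGORIES)
            assert table.loc[(arm, "total"), "mean"] == pytest.approx(cat_sum, abs=1e-12)

    def test_single_participant_year_flags_undefined_sd(self):
        records = [make_record(id="c", arm="control", costs={1: 100.0}),
                   make_record(id="i", arm="intervention", costs={1: 80.0})]
        table = summarize_annual_costs(cohort_of(*records))
        assert table["sd"].isna().all()
        assert (table.n_participant_years == 1).all()

    def test_empty_arm_raises(self):
        with pytest.raises(EstimationError, match="control"):
            summarize_annual_costs(cohort_of(make_record(arm="intervention", costs={1: 1.0})))


class TestKMSamplingAverage:
    def test_no_censoring_reduces_to_plain_mean(self, tiny_cohort):
        complete = cohort_of(*[r for r in tiny_cohort if r.censor_year is None])
        for arm in ("intervention", "control"):
            est = km_sampling_average(complete, arm, 2)
            expected = np.mean([sum(r.annual_costs[2].values())
                                for r in complete.arm(arm)])
            assert est.total_mean == pytest.approx(expected)
            assert est.n_observed == len(complete.arm(arm))

    def test_three_observed_totals_average(self):
        records = [make_record(id=f"c{i}", arm="control", costs={2: v})
                   for i, v in enumerate([100.0, 200.0, 300.0])]
        assert km_sampling_average(cohort_of(*records), "control", 2).total_mean == 200.0

    def test_censored_high_cost_participants_excluded_from_later_years(self):
        """Year-3 estimate is the brute-force mean over the still-observed subset."""
        high = [make_record(id=f"h{i}", arm="control", censor_year=2,
                            costs={1: 5000.0, 2: 5000.0}) for i in range(3)]
        low = [make_record(id=f"l{i}", arm="control",
                           costs={1: 100.0, 2: 100.0, 3: 150.0 + i}) for i in range(4)]
        est = km_sampling_average(cohort_of(*high, *low), "control", 3)
        assert est.n_observed == 4
        assert est.total_mean == pytest.approx(np.mean([150.0, 151.0, 152.0, 153.0]))

    def test_no_observations_error_names_arm_and_year(self):
        cohort = cohort_of(make_record(arm="control", censor_year=1, costs={1: 10.0}))
        with pytest.raises(EstimationError, match="control.*year=3"):
            km_sampling_average(cohort, "control", 3)


class TestRemissionCostSaving:
    def _cohort_with_ratios(self, ratios):
        """Non-remission mean 1000 each year; remission mean = ratio x 1000."""
        records = []
        for y, ratio in zip(range(2, 6), ratios):
            records.append(make_record(id=f"n{y}", arm="control",
                                       costs={k: 1000.0 for k in range(1, 6)}))
            rec = make_record(id=f"r{y}", arm="intervention", remission_12m=True,
                              costs={k: 0.0 for k in range(1, 6)})
            for k in range(1, 6):
                rec.annual_costs[k]["primary_care"] = 1000.0 * ratios[min(k - 2, 3)] if k >= 2 else 500.0
            records.append(rec)
        return cohort_of(*records)

    def test_equal_costs_give_zero_saving(self):
        cohort = self._cohort_with_ratios([1.0, 1.0, 1.0, 1.0])
        assert remission_cost_saving_fraction(cohort) == 0.0

    def test_half_costs_give_half_saving(self):
        cohort = self._cohort_with_ratios([0.5, 0.5, 0.5, 0.5])
        assert remission_cost_saving_fraction(cohort) == pytest.approx(0.5)

    def test_mean_of_yearly_ratios(self):
        cohort = self._cohort_with_ratios([0.8, 0.6, 0.7, 0.9])
        assert remission_cost_saving_fraction(cohort) == pytest.approx(1 - np.mean([0.8, 0.6, 0.7, 0.9]))

    def test_zero_nonremission_mean_raises(self):
        records = [
            make_record(id="n", arm="control", costs={y: 0.0 for y in range(1, 6)}),
            make_record(id="r", arm="intervention", remission_12m=True,
                        costs={y: 100.0 for y in range(1, 6)}),
        ]
        with pytest.raises(EstimationError, match="zero"):
            remission_cost_saving_fraction(cohort_of(*records))


def test_costed_outputs_non_negative(tiny_cohort, uc):
    for r in tiny_cohort.arm("intervention"):
        assert all(v >= 0 for v in cost_intervention(r, uc).values())
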