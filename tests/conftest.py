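import numpy as np
import pytest

from remicea import defaults
from remicea.config import COST_CATEGORIES, Cohort, ParticipantRecord
from remicea.synthetic import generate_cohort


@pytest.fixture(scope="session")
def packaged():
    """Packaged default inputs: (unit costs, mortality, utility norms)."""
    return defaults.unit_costs(), defaults.mortality(), defaults.utility_norms()


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small uncalibrated cohort for fast estimator tests."""
    return generate_cohort(defaults.generator_params(seed=11, n_per_arm=40, calibrate=False))


@pytest.fixture(scope="session")
def calibrated_cohort():
    """Full-size calibrated base-case cohort (moment-matched to the defaults)."""
    return generate_cohort(defaults.generator_params(seed=5))


def make_record(id="X001", arm="control", remission_12m=False, relapse_year=None,
                censor_year=None, annual_status=None, costs=None, sachets=None,
                visits=None, eq5d=None, extension=False, sex="F"):
    """Hand-built participant with explicit costs {year: total or per-category}."""
    annual_costs = {}
    for y, v in (costs or {}).items():
        if isinstance(v, dict):
            annual_costs[y] = {c: float(v.get(c, 0.0)) for c in COST_CATEGORIES}
        else:  # scalar: put everything in primary care
            annual_costs[y] = {c: 0.0 for c in COST_CATEGORIES}
            annual_costs[y]["primary_care"] = float(v)
    return ParticipantRecord(
        id=id, arm=arm, sex=sex, age_at_entry=54.0, extension_participant=extension,
        remission_12m=remission_12m, relapse_year=relapse_year, censor_year=censor_year,
        annual_costs=annual_costs, sachets=sachets or {}, visits=visits or {},
        eq5d=eq5d or [], annual_status=annual_status or {},
    )


def cohort_of(*records):
    return Cohort(list(records))
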