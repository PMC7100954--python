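import numpy as np
import pytest

from msmpub.records import (
    Collaboration,
    CovariateVector,
    Funding,
    Status,
    StudyRecord,
)
from msmpub.simulate import SimulationScenario, simulate_cohort


def make_record(**kwargs) -> StudyRecord:
    base = dict(
        study_id="S1",
        approval_year=2000,
        followup_end_year=2011,
        status=Status.COMPLETED,
        completion_year=2003,
        publication_year=2005,
        rct=True,
        sample_size=120,
        funding=Funding.NONCOMMERCIAL,
        industry_involved=False,
        collaboration=Collaboration.SINGLE_CENTRE,
        primary_outcome=True,
    )
    base.update(kwargs)
    return StudyRecord(**base)


def make_covariates(**kwargs) -> CovariateVector:
    base = dict(
        log_sample_size=np.log(120.0),
        rct=0,
        funding_commercial=0,
        funding_not_reported=0,
        industry=0,
        primary_outcome=0,
        collab_multi_national=0,
        collab_multi_international=0,
    )
    base.update(kwargs)
    return CovariateVector(**base)


@pytest.fixture(scope="session")
def fixture_cohort():
    """Small synthetic cohort with a fixed seed, shared across tests."""
    scenario = SimulationScenario(n_studies=200, seed=20260901)
    records, truth = simulate_cohort(scenario)
    return records, truth, scenario
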