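import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import triage_sim as ts

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: Seed of the packaged default fixture used across the suite.
FIXTURE_SEED = 1


def make_scored(
    pid="p",
    age=60.0,
    saps=35.0,
    tiss=9.0,
    n_secondary=12,
    covid=False,
    icu_los=4,
    hosp_los=18,
    died=False,
):
    """ScoredPatient factory with sensible cohort-typical defaults."""
    prepared = ts.PreparedPatient(
        patient_id=pid,
        age=age,
        saps=saps,
        tiss=tiss,
        n_secondary=n_secondary,
        covid=covid,
        icu_los=icu_los,
        hosp_los=hosp_los,
        died=died,
    )
    from triage_sim.scoring import score_patient

    return score_patient(prepared)


@pytest.fixture(scope="session")
def default_records():
    """The packaged raw-export fixture: generator defaults, fixed seed."""
    return ts.generate_cohort(ts.GeneratorParams(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def prepared_cohort(default_records):
    kept, report = ts.filter_and_prepare(default_records)
    return kept, report


@pytest.fixture(scope="session")
def scored_cohort(prepared_cohort):
    kept, _ = prepared_cohort
    return ts.score_patients(kept)


@pytest.fixture(scope="session")
def cohort_matrix(scored_cohort):
    return ts.CohortMatrix(scored_cohort)


@pytest.fixture(scope="session")
def study_results(cohort_matrix):
    """Reduced-size full-factorial study shared by the acceptance suite."""
    config = ts.SimConfig(n_runs=150, seed=11)
    return ts.run_study(cohort_matrix, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
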