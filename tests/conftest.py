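import numpy as np
import pytest

import rabepkpd as r


@pytest.fixture(scope="session")
def pop():
    return r.published_pk()


@pytest.fixture(scope="session")
def pd_params():
    return r.published_pd()


@pytest.fixture(scope="session")
def typical_male(pop):
    cov = r.SubjectCovariates(gender="male", bsa=1.87)
    return r.individual_parameters(pop, cov)


@pytest.fixture(scope="session")
def dose_10mg():
    return r.DoseEvent.from_mg(10.0)


@pytest.fixture(scope="session")
def study_trial(pop):
    """A default-design synthetic trial (24 M / 21 F, 10 mg single dose)."""
    spec = r.CohortSpec(seed=202)
    cohort = r.generate_cohort(spec, np.random.default_rng(202))
    return r.simulate_trial(cohort, pop, spec, seed=203)
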