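import numpy as np
import pytest

from glutme import generate_bulk_cohort, generate_response_cohort, generate_sc_cohort, score_cohort
from glutme.synthetic import BulkSimParams, ResponseSimParams, ScSimParams

BULK_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def bulk_cohorts_scored():
    """Default bulk cohorts for seeds 1-5, each with its enrichment table."""
    out = {}
    for seed in BULK_SEEDS:
        cohort = generate_bulk_cohort(BulkSimParams(seed=seed))
        scores = score_cohort(cohort.expression, cohort.signatures, alpha=0.25)
        out[seed] = (cohort, scores)
    return out


@pytest.fixture(scope="session")
def bulk_cohort(bulk_cohorts_scored):
    return bulk_cohorts_scored[1][0]


@pytest.fixture(scope="session")
def bulk_scores(bulk_cohorts_scored):
    return bulk_cohorts_scored[1][1]


@pytest.fixture(scope="session")
def sc_cohort():
    return generate_sc_cohort(ScSimParams(seed=0))


@pytest.fixture(scope="session")
def response_sim():
    """Default immunotherapy cohort at the size the waterfall properties are stated for."""
    return generate_response_cohort(ResponseSimParams(n_patients=1000, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260918)
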