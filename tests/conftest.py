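import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from tedscore.synthetic import (expand_quartile_fixture, expand_score_fixture,
                                load_fixtures)


@pytest.fixture(scope="session")
def bundle():
    return load_fixtures()


@pytest.fixture(scope="session")
def score_records(bundle):
    """31 (composite score, responder) pairs from the published table."""
    return expand_score_fixture(bundle)


@pytest.fixture(scope="session")
def quartile_records(bundle):
    """31 (TSAb quartile, responder) pairs from the published table."""
    return expand_quartile_fixture(bundle)


@pytest.fixture(scope="session")
def score_arrays(score_records):
    scores = np.array([r[0] for r in score_records], dtype=float)
    responder = np.array([r[1] for r in score_records])
    return scores, responder
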