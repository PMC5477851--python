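import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import centrosurv as cs

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort() -> cs.SyntheticCohort:
    """A modest cohort with the default (study-condition) parameters."""
    return cs.generate_cohort(cs.SyntheticCohortConfig(n_samples=120, seed=7))


@pytest.fixture(scope="session")
def null_cohort() -> cs.SyntheticCohort:
    """A cohort with no KIFC1-survival association."""
    return cs.generate_cohort(
        cs.SyntheticCohortConfig(n_samples=120, true_log_hr=0.0, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def padded_matrix(small_cohort):
    """Cohort expression plus 200 independent noise genes (for GSEA)."""
    rng = np.random.default_rng(99)
    extra = pd.DataFrame(
        rng.standard_normal((200, small_cohort.expression.shape[1])) + 7.0,
        index=[f"RND{i:03d}" for i in range(200)],
        columns=small_cohort.expression.columns,
    )
    return pd.concat([small_cohort.expression, extra])
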