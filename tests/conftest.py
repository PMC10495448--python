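import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tp53tx.synthetic import CohortConfig, generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250927)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort (fast) with every status represented."""
    return generate_cohort(
        CohortConfig(
            n_samples=200,
            prevalence_biallelic=0.08,
            prevalence_monoallelic=0.15,
            n_background_genes=60,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def study_scale_cohort():
    """A cohort at the default study-scale conditions (shared, read-only)."""
    return generate_cohort(CohortConfig(n_samples=600, n_background_genes=120, seed=3))
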