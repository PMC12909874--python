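import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_pool():
    """Shared synthetic triage pool (built once; several suites read it)."""
    from seqtriage.simulate import make_candidate_pool

    return make_candidate_pool(seed=20240901 % 1000)


@pytest.fixture(scope="session")
def small_pool_result(small_pool):
    from seqtriage import TriageConfig, run_pipeline

    config = TriageConfig(length_bounds=(95, 105))
    return run_pipeline(
        small_pool.candidates,
        small_pool.references,
        small_pool.plddt,
        anchor=small_pool.anchor,
        config=config,
    )
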