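import numpy as np
import pytest

from mmrtriage import (
    CohortConfig,
    NoiseConfig,
    PipelineConfig,
    apply_qc_filter,
    generate_cohort,
    run_pipeline,
)


@pytest.fixture
def small_config():
    """A miniature cohort: fast, but structurally complete."""
    return CohortConfig(
        n_patients=5,
        n_deficient=2,
        n_routine_cores=40,
        n_overfixed_cores=10,
        n_quantified=None,
        cores_per_block=12,
    )


@pytest.fixture
def small_cohort(small_config):
    return generate_cohort(small_config, seed=7)


@pytest.fixture
def small_cohort_qc(small_cohort):
    return apply_qc_filter(small_cohort)


@pytest.fixture(scope="session")
def study_cohort():
    """The study-shaped default cohort (11 patients, 3 deficient,
    623 routine + 337 over-fixed cores)."""
    return generate_cohort(CohortConfig(), seed=11)


@pytest.fixture(scope="session")
def default_pipeline_result():
    """One full default pipeline run shared across tests."""
    return run_pipeline(PipelineConfig(), seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
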