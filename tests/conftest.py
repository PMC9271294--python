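import numpy as np
import pytest

from psyatlas import CohortSpec, RunConfig, SOMConfig, generate_cohort, run_pipeline


def small_spec(**overrides) -> CohortSpec:
    """A fast, structurally faithful cohort for unit tests."""
    defaults = dict(n_train=400, n_test_depressed=80, n_test_nondepressed=160, seed=7)
    defaults.update(overrides)
    return CohortSpec(**defaults)


@pytest.fixture(scope="session")
def study_cohort():
    """The full study-condition cohort: 2718 train / 394+779 test."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def atlas_bundle():
    """End-to-end pipeline on the study cohort with a 12x12 map.

    Session-scoped: the SOM training and overlay are shared by the atlas,
    path and acceptance tests.
    """
    config = RunConfig(seed=3, som_config=SOMConfig(width=12, height=12))
    return run_pipeline(config)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
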