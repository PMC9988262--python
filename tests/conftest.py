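import numpy as np
import pytest

from brainage.synthetic_cohort import CohortSpec, generate_cohort_full


def tiny_spec(**overrides) -> CohortSpec:
    """Desk-corner cohort: big enough to fit models, small enough for seconds."""
    base = dict(n_train=80, n_per_group=(25, 25, 25), n_roi=12,
                n_struct_thickness=12, n_struct_volume=6, n_sites=2, seed=0)
    base.update(overrides)
    return CohortSpec(**base)


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort_full(tiny_spec(seed=5))


@pytest.fixture(scope="session")
def default_cohort():
    """One full-scale cohort shared by the slower integration tests."""
    return generate_cohort_full(CohortSpec(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
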