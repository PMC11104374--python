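import numpy as np
import pytest

TABLE1_PERCEPTUAL = dict(kappa2=0.5, omega2=-2.0, theta=0.5, mu2_0=0.0,
                         sigma2_0=1.0, mu3_0=1.0, sigma3_0=1.0)


@pytest.fixture
def table1_params():
    return dict(TABLE1_PERCEPTUAL)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Ten mean-reverting agents on the default schedule (session-scoped:
    several test modules reuse it to keep runtime down)."""
    from hgflearn.task import CohortSpec, GroupSpec, generate_cohort

    spec = CohortSpec(
        groups=(GroupSpec(name="agents", n_subjects=10, model="HII",
                          param_sds={"m3": 2.0}),),
        seed=77,
    )
    return generate_cohort(spec)
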