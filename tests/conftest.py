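import numpy as np
import pytest

from glucest.phantom import (
    DEFAULT_POOLS,
    CohortSpec,
    PoolParams,
    calibrate_glu_amplitude,
    generate_cohort,
    make_label_map,
)
from glucest.zspec import cest_axis, wassr_axis

SMALL_SHAPE = (48, 48)


@pytest.fixture(scope="session")
def axis_cest():
    return cest_axis()


@pytest.fixture(scope="session")
def axis_wassr():
    return wassr_axis()


@pytest.fixture(scope="session")
def label_map_small():
    return make_label_map(0, SMALL_SHAPE)


@pytest.fixture(scope="session")
def glu_pool():
    return PoolParams("glutamate", 3.0, 1.0, 0.05)


@pytest.fixture(scope="session")
def calibrated_pools():
    """Default fixed pools plus a glutamate pool calibrated to 0.025."""
    amp = calibrate_glu_amplitude(0.025)
    return list(DEFAULT_POOLS) + [PoolParams("glutamate", 3.0, 1.0, amp)]


def small_cohort(genotype="AD", age=2, n=1, sigma=0.0, b0=0.0, seed=0,
                 shape=SMALL_SHAPE):
    spec = CohortSpec.from_defaults(genotype, age, n_subjects=n,
                                    noise_sigma=sigma, b0_amplitude=b0,
                                    seed=seed, shape=shape)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def subject_zero_b0():
    """One noiseless zero-B0 AD/2-month subject on the small grid."""
    return small_cohort()[0]


@pytest.fixture(scope="session")
def subject_with_b0():
    """One noiseless subject with a 0.2 ppm peak smooth B0 field."""
    return small_cohort(genotype="WT", age=12, b0=0.2)[0]
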