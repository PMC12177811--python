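import numpy as np
import pytest

from tractcrowd.synthetic_data import CohortSpec, make_arc_bundle


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    return CohortSpec(
        n_group_a=4,
        n_group_b=4,
        streamlines_per_bundle=30,
        jitter_sd_mm=1.0,
        outlier_fraction=0.0,
        seed=1,
    )


@pytest.fixture
def noiseless_spec():
    return CohortSpec(
        n_group_a=4,
        n_group_b=4,
        streamlines_per_bundle=20,
        jitter_sd_mm=1e-9,
        outlier_fraction=0.0,
        seed=1,
    )


@pytest.fixture
def arc_bundle(small_spec, rng):
    return make_arc_bundle(small_spec, "left", rng)


@pytest.fixture
def noiseless_bundle(noiseless_spec, rng):
    return make_arc_bundle(noiseless_spec, "left", rng)
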