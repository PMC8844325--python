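import numpy as np
import pytest

from mbfvs.imaging import make_schedule, pet_sum
from mbfvs.phantom import (
    InputFunctionParams,
    PhantomSpec,
    generate_anatomy,
    simulate_dynamic_pet,
)


@pytest.fixture(scope="session")
def schedule_snuh():
    return make_schedule("SNUH")


@pytest.fixture(scope="session")
def input_params():
    return InputFunctionParams()


@pytest.fixture(scope="session")
def phantom_default():
    """Default 96^3 / 2 mm phantom (10 mm wall)."""
    spec = PhantomSpec(seed=11)
    masks, truth = generate_anatomy(spec)
    return spec, masks, truth


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(
        grid_shape=(64, 64, 64),
        voxel_size_mm=3.0,
        lv_radius_mm=18.0,
        rv_radius_mm=12.0,
        wall_thickness_mm=9.0,
        apex_extent_mm=50.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def phantom_small(small_spec):
    masks, truth = generate_anatomy(small_spec)
    return masks, truth


@pytest.fixture(scope="session")
def series_clean(phantom_small, input_params, schedule_snuh):
    masks, truth = phantom_small
    return simulate_dynamic_pet(
        masks, truth, input_params, schedule_snuh, state="stress", noise_scale=0.0
    )


@pytest.fixture(scope="session")
def series_noisy(phantom_small, input_params, schedule_snuh):
    masks, truth = phantom_small
    return simulate_dynamic_pet(
        masks, truth, input_params, schedule_snuh, state="stress", noise_scale=0.5, seed=2
    )


@pytest.fixture(scope="session")
def psum_noisy(series_noisy):
    return pet_sum(series_noisy)
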