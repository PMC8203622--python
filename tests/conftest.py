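import numpy as np
import pytest

from tightdock.synthetic import (
    BilayerFrameSpec,
    docked_pair_spec,
    free_vesicle_spec,
    generate_bilayer_frame,
    generate_vesicle_pair_image,
)


@pytest.fixture(scope="session")
def free_vesicle_noiseless():
    spec = free_vesicle_spec(noise_sigma=0.0, seed=11)
    return generate_vesicle_pair_image(spec) + (spec,)


@pytest.fixture(scope="session")
def tight_pair():
    spec = docked_pair_spec("tight", seed=12)
    return generate_vesicle_pair_image(spec) + (spec,)


@pytest.fixture(scope="session")
def loose_pair():
    spec = docked_pair_spec("loose", seed=13)
    return generate_vesicle_pair_image(spec) + (spec,)


@pytest.fixture(scope="session")
def double_bilayer_frame():
    spec = BilayerFrameSpec(
        n_membranes=2,
        thickness_nm=4.2,
        intermembrane_distance_nm=0.5,
        mean_tilt_cos=(0.6, 0.9),
        n_gap_waters=50,
        seed=21,
    )
    return generate_bilayer_frame(spec), spec


@pytest.fixture(scope="session")
def single_bilayer_frame():
    spec = BilayerFrameSpec(n_membranes=1, thickness_nm=4.2, seed=22)
    return generate_bilayer_frame(spec), spec


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
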