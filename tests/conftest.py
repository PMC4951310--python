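import numpy as np
import pytest

from stromascope import ImageSimParams, generate_core_image, separate_core


@pytest.fixture(scope="session")
def noiseless_scene():
    """A standard noiseless five-vessel core shared by geometry tests."""
    params = ImageSimParams(
        core_diameter_um=300.0, n_vessels=5, noise_sd=0.0,
        stroma_fraction_target=0.25, seed=11,
    )
    image, gt = generate_core_image(params)
    return params, image, gt


@pytest.fixture(scope="session")
def noiseless_channels(noiseless_scene):
    _, image, _ = noiseless_scene
    return separate_core(image)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
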