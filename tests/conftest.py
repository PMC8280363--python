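import numpy as np
import pytest

from pdtplan import LEDArray, LEDSpec, make_lesion_patch


@pytest.fixture(scope="session")
def default_array() -> LEDArray:
    """15 x 15 panel, 10 mm pitch, 15-degree half angle, 372 mW/Sr."""
    return LEDArray.grid(spec=LEDSpec())


@pytest.fixture(scope="session")
def lesion_patch():
    """Default synthetic lesion-site patch (seed 0): skin-toned curved patch
    with an irregular painted lesion and ground-truth mask."""
    return make_lesion_patch(seed=0)


@pytest.fixture(scope="session")
def lesion_cloud(lesion_patch):
    """The painted lesion sub-cloud (ground truth), the planning target."""
    return lesion_patch.select(lesion_patch.attributes["lesion_mask"])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
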