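import numpy as np
import pytest

from coccoquant import phantom
from coccoquant.image_core import RegionMask


@pytest.fixture(scope="session")
def default_phantom():
    """Default cell phantom (10 M body, 1.5 M cloud) built once per session."""
    return phantom.make_cell_phantom()


@pytest.fixture(scope="session")
def default_truth(default_phantom):
    return default_phantom[1]


@pytest.fixture(scope="session")
def truth_13p4():
    """Phantom with the Ca-P body planted at 13.4 M for the X-ray loop."""
    cfg = phantom.PhantomConfig(body_molarity_M=13.4)
    return phantom.make_cell_phantom(cfg)[1]


def standard_regions(truth):
    """(name, material, mask) triples for the three in-image standards."""
    return [
        ("lipid", truth.materials[4], RegionMask(truth.mask("lipid"), "lipid")),
        ("medium", truth.materials[0], RegionMask(truth.mask("medium"), "medium")),
        ("calcite", truth.materials[5], RegionMask(truth.mask("coccolith"), "coccolith")),
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
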