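import numpy as np
import pytest
from hypothesis import settings

import spidiff as sp

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def front_geom():
    """Wide-angle geometry with the beam centre in a corner, so pixel
    radii up to ~265 px exist on a modest grid."""
    return sp.front_detector(n_rows=300, n_cols=300, beam_center=(0.0, 0.0))


@pytest.fixture(scope="session")
def back_geom():
    return sp.back_detector(256, 256)


@pytest.fixture(scope="session")
def back_map(back_geom):
    return sp.build_pixel_map(back_geom)


@pytest.fixture(scope="session")
def back_config():
    return sp.ShotConfig(seed=11)


@pytest.fixture(scope="session")
def back_mask(back_geom, back_config):
    from spidiff.simulator import detector_mask

    return detector_mask(back_geom, back_config)


@pytest.fixture(scope="session")
def back_fitter(back_map, back_mask):
    return sp.SphereFitter(back_map, mask=back_mask)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
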