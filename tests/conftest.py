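import numpy as np
import pytest

from wcdcm.generative import default_input_timeline, make_ground_truth_network


@pytest.fixture(scope="session")
def gt_bilinear():
    return make_ground_truth_network(variant="bilinear")


@pytest.fixture(scope="session")
def gt_wc():
    return make_ground_truth_network(variant="wilson_cowan")


@pytest.fixture(scope="session")
def timeline_short():
    """Half-length run used where speed matters more than precision."""
    return default_input_timeline(180.0, dt=0.25)


@pytest.fixture(scope="session")
def timeline_full():
    """Standard 6-minute run at TR/8 microtime."""
    return default_input_timeline(360.0, dt=0.25)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
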