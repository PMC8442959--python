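import numpy as np
import pytest

from cardioreg import phantom as ph


@pytest.fixture(scope="session")
def small_geometry():
    """Compact 24^3 shell used by most unit tests."""
    return ph.make_lv_geometry((24, 24, 24), (1.0, 1.0, 1.0),
                               (6.0, 6.0, 8.0), (9.0, 9.0, 10.0))


@pytest.fixture(scope="session")
def small_motion():
    return ph.MotionParams(n_frames=10, es_frame=4)


@pytest.fixture(scope="session")
def small_truth(small_geometry, small_motion):
    return ph.make_ground_truth_motion(small_geometry, small_motion)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
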