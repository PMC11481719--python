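import numpy as np
import pytest

import fearscope as fs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fc_schedule():
    return fs.make_fc_schedule()


@pytest.fixture(scope="session")
def fe_schedule():
    return fs.make_fe_schedule()


@pytest.fixture(scope="session")
def short_imo():
    """A 2 x 60 s restraint session — long enough for every stage, short
    enough to keep the suite fast."""
    return fs.make_imo_schedule(epoch_s=60.0)


@pytest.fixture(scope="session")
def small_video():
    frames, gt = fs.simulate_movement_video(400, seed=21)
    return frames, gt
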