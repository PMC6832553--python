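import numpy as np
import pytest

import glmbtrack as g


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def scalar_obs():
    """1-D linear observation H=1, R=1 on a 1-D state."""
    return g.ObservationModel(kind="linear", H=np.eye(1), R=np.eye(1))


@pytest.fixture
def small_linear_models():
    """2-D position tracking world with mild clutter, for tiny filter tests."""
    motion = g.make_cv_model(1.0, 1.0)
    obs = g.make_linear_position_model(1.0, state_dim=4)
    clutter = g.ClutterModel(
        rate=2.0, support=g.models.RectSupport([-50.0, -50.0], [50.0, 50.0])
    )
    det = g.DetectionModel(p_d=0.9, p_s=0.95)
    birth = g.BirthModel(components=[])
    return g.ModelSet(motion=motion, obs=obs, birth=birth, clutter=clutter, detection=det)
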