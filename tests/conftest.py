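import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_pelvis():
    """A noise-free synthetic pelvis with known (30, 40, 5) angles on both sides."""
    from hipdx.angles import AngleTriplet
    from hipdx.synthetic import PelvisSimConfig, construct_pelvis

    cfg = PelvisSimConfig(
        target_right=AngleTriplet(30.0, 40.0, 5.0),
        target_left=AngleTriplet(30.0, 40.0, 5.0),
        contour_points=360,
    )
    ann, truth = construct_pelvis(cfg)
    return ann, truth
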