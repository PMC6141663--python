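import numpy as np
import pytest

from vesiquant import RegionOfInterest, SimulationConfig, simulate_ldcv_movie


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_event_movie():
    """200-frame TIRF movie, 10 spots, 3 scheduled events, no noise."""
    cfg = SimulationConfig(
        n_spots=10, n_frames=200, stim_onset=5.0, seed=1,
        event_schedule=((2.0, 0, "full_fusion"),
                        (5.0, 3, "kiss_and_run"),
                        (8.0, 7, "full_fusion")))
    return simulate_ldcv_movie(cfg)


@pytest.fixture
def full_footprint():
    def make(movie):
        return RegionOfInterest("label_mask",
                                mask=np.ones(movie.shape[1:], dtype=bool))
    return make
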