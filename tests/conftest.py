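import numpy as np
import pytest
from hypothesis import settings

import spikewell as sw

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_train(times, eid="A1_11"):
    return sw.SpikeTrain(eid, np.asarray(times, dtype=float))


@pytest.fixture
def small_recording():
    """Two wells of four electrodes, 20 s, simple regular trains."""
    trains = {}
    for w, base in (("A1", 0.0), ("A2", 0.1)):
        for k in range(4):
            eid = f"{w}_1{k + 1}"
            trains[eid] = make_train(base + np.arange(0.5, 19.5, 0.2 + 0.01 * k), eid)
    return sw.Recording.from_trains(trains, start_time=0.0, end_time=20.0,
                                    label="rec1")


@pytest.fixture(scope="session")
def simulated_recording():
    cfg = sw.SimConfig(n_wells=4, duration=120.0, background_rate=1.0,
                       burst_rate_per_min=4.0, nb_rate_per_min=2.0, seed=7)
    rec, truth = sw.simulate_recording(cfg)
    return rec, truth
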