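import numpy as np
import pytest

import cerebconn as cc


@pytest.fixture(scope="session")
def parcels20():
    return cc.make_parcel_set(20, seed=7)


@pytest.fixture(scope="session")
def parcels80():
    return cc.make_parcel_set(80, seed=7)


@pytest.fixture(scope="session")
def small_study(parcels20):
    """Convergent-truth study at a size every unit test can afford."""
    truth = cc.make_ground_truth(parcels20, 30, "convergent", seed=3)
    return cc.simulate_study("A", parcels20, truth, seed=5)


@pytest.fixture(scope="session")
def small_pairs(small_study):
    fits = [cc.reconstruct_session(s) for s in small_study.sessions]
    return cc.make_crossed_pairs(fits[0], fits[1])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
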