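import numpy as np
import pytest

from switchlead import SwitchSchedule, VicsekParams, simulate_vicsek


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def vicsek_pair_constant():
    """One seeded constant-leader pair run (post-transient turn rates)."""
    params = VicsekParams(seed=1234)
    return simulate_vicsek(params, SwitchSchedule([(0, [0])]))


@pytest.fixture(scope="session")
def vicsek_pair_switch():
    """One seeded pair run with a leadership switch at post-transient step 10,000."""
    params = VicsekParams(seed=4321)
    schedule = SwitchSchedule([(0, [0]), (20_000, [1])])
    return simulate_vicsek(params, schedule), schedule.shift(10_000)
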