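import numpy as np
import pytest

import fpvs


@pytest.fixture(scope="session")
def spike_schedule():
    return fpvs.make_spike_schedule()


@pytest.fixture(scope="session")
def bold_schedule():
    return fpvs.make_bold_schedule()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def simulate_unit(schedule, rng, n_sequences=2, **params):
    """Two 70 s sequences for one unit with the given generative parameters."""
    p = fpvs.UnitSimParams(**params)
    return [
        fpvs.simulate_spike_train(schedule, p, rng, sequence_id=k)
        for k in range(n_sequences)
    ]
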