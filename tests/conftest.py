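import numpy as np
import pytest

import spikeswitch as ss


@pytest.fixture(scope="session")
def demo_session():
    """Small synthetic session: 2 neurons per mechanism + 2 null,
    8 TRO levels x 20 trials."""
    return ss.generate_session(
        ss.BehaviorParams(trials_per_level=20),
        ss.demo_neuron_specs(n_per_mechanism=2, n_null=2),
        seed=1234,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
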