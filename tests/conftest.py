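import numpy as np
import pytest

from painlfp import synth


@pytest.fixture(scope="session")
def demo_session():
    """A small but complete two-region session with ground truth."""
    scn = synth.Scenario(n_evoked=12, n_spontaneous=6, control_lead=60.0)
    sess, truth = synth.generate_session(scn, seed=7)
    return sess, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
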