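import numpy as np
import pytest

from mesovasc import synth


@pytest.fixture(scope="session")
def small_whisker_session():
    """Small-canvas whisker session with a planted 3% GCaMP response."""
    cfg = synth.WidefieldConfig(shape=(64, 86), n_trials=8, snr=10)
    return synth.gen_widefield_session(cfg, seed=101)


@pytest.fixture(scope="session")
def small_hc_session():
    """Small-canvas hypercapnia session with 2% tissue plateaus."""
    cfg = synth.WidefieldConfig(kind="hypercapnia", shape=(64, 86))
    return synth.gen_widefield_session(cfg, seed=102)


@pytest.fixture(scope="session")
def twophoton_volume():
    return synth.gen_twophoton_volume(seed=103)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
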