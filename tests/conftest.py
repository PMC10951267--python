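import numpy as np
import pytest

import temposample as ts


@pytest.fixture(scope="session")
def paperlike_observer():
    return ts.make_paperlike_observer(seed=0)


@pytest.fixture(scope="session")
def small_word_bank():
    """20 rendered pseudo-words at a coarse scale (fast to correlate)."""
    words = ts.demo_words(20, seed=3)
    return {w: ts.render_word_image(w, px_per_deg=12.0) for w in words}


@pytest.fixture(scope="session")
def cohort_16(paperlike_observer):
    """16 simulated participants x 4 conditions x 150 fixed-contrast trials."""
    data, obs = ts.simulate_cohort(
        16, 150, seed=31, observer=paperlike_observer, jitter=0.1
    )
    return data, obs


@pytest.fixture(scope="session")
def cohort_zcis_tf(cohort_16):
    data, _ = cohort_16
    return ts.cohort_zcis(data, domain="time_frequency", n_boot=300, seed=7)


@pytest.fixture(scope="session")
def cohort_zcis_time(cohort_16):
    data, _ = cohort_16
    return ts.cohort_zcis(data, domain="time", n_boot=300, seed=8)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
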