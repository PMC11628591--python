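import numpy as np
import pytest

from ttcseg import synthdata


@pytest.fixture(scope="session")
def small_cohort():
    """Four phantom hearts at 128 px — enough structure for most tests."""
    cfg = synthdata.PhantomConfig(n_experiments=4, image_size=128, seed=11)
    return synthdata.generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
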