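import numpy as np
import pytest

from culmfit import SyntheticConfig, generate


@pytest.fixture(scope="session")
def default_records():
    """Synthetic 45-culm sample under the study conditions, fixed seed."""
    return generate(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def noisefree_records():
    """Culms lying exactly on the true power laws (all error scales zero)."""
    cfg = SyntheticConfig(
        seed=7,
        error_scales={"culm": 0.0, "branch": 0.0, "leaf": 0.0},
        height_sigma=0.0,
    )
    return generate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
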