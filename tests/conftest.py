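import numpy as np
import pytest

from mucoswim import CoatingParams, make_mucus_field


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def homogeneous_fluid():
    """Uniform mucus (mobility 1 everywhere) over a generous extent."""
    return make_mucus_field(
        extent=(-300.0, 300.0, -300.0, 300.0), grid_step=10.0, cv=0.0, seed=0
    )


@pytest.fixture
def plain_coating():
    """Noise-free linear coating: speed = 0.3 * f below step-out at 60 Hz."""
    return CoatingParams(name="plain", c=0.3, f_c0=60.0, p=0.0, sigma_U=0.0)
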