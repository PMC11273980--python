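import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def zero_conv_weights(module):
    """Zero every conv/dense weight and bias, keep BN at initialization."""
    for name, p in module.named_parameters():
        leaf = name.rsplit(".", 1)[-1]
        if leaf in ("weight", "bias"):
            p.data[...] = 0.0
    return module


@pytest.fixture
def make_zeroed():
    return zero_conv_weights
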