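import numpy as np
import pytest

import mscaseg as m


@pytest.fixture(scope="session")
def phantom_cfg():
    return m.PhantomConfig(
        shape=(64, 64, 64),
        bias_coeffs={(1, 0, 0): 0.15, (0, 1, 0): -0.1},
    )


@pytest.fixture(scope="session")
def phantom_pair(phantom_cfg):
    """A deterministic 64^3 phantom with exact labels."""
    return m.generate_phantom(phantom_cfg, seed=11)


@pytest.fixture(scope="session")
def tiny_arch():
    return m.ArchConfig.tiny()


@pytest.fixture(scope="session")
def tiny_net(tiny_arch):
    """A fixed, untrained tiny network; tests must not mutate its weights."""
    return m.build_network(tiny_arch, seed=3)
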