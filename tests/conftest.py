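import numpy as np
import pytest

from slabimpute import (PhantomSpec, SynthConfig, UNet, UNetConfig,
                        generate_phantom)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_phantom():
    """Compact folded phantom: 32x32 in-plane (divisible by 16), 40 mm AP."""
    return generate_phantom(PhantomSpec(grid_shape=(32, 32, 40), seed=7))


@pytest.fixture(scope="session")
def tiny_net():
    """Small random-weight network for shape/permutation tests."""
    net = UNet(UNetConfig(base_channels=4, dtype="float64"), seed=5)
    # give the head nonzero weights so the residual path is exercised
    head_rng = np.random.default_rng(11)
    net.head.W[...] = 0.05 * head_rng.standard_normal(net.head.W.shape)
    return net


@pytest.fixture(scope="session")
def zero_head_net():
    return UNet(UNetConfig(base_channels=4, dtype="float64"), seed=5)


def make_ramp_volume(shape=(16, 16, 40), slope=2.0, offset=1.0):
    """Volume affine in the AP coordinate: v(x, y, z) = offset + slope*z."""
    vol = np.zeros(shape)
    vol[:] = offset + slope * np.arange(shape[2])[None, None, :]
    return vol
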