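import numpy as np
import pytest
from hypothesis import settings

from arterysph.kernels import KernelSet

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

H = 0.025  # reference kernel radius (m)


@pytest.fixture(scope="session")
def kernels() -> KernelSet:
    return KernelSet(H)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
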