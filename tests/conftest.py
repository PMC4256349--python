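import numpy as np
import pytest

from oamspin import PeldorTiming


@pytest.fixture
def exp_timing() -> PeldorTiming:
    """Reported acquisition timing: 148 points in 8-ns steps, tau = 200 ns."""
    return PeldorTiming(tau=200.0, T=1100.0, dt=8.0, n_points=148)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
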