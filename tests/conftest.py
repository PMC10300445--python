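import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rank1_instance(rng, max_dim=4, max_T=8):
    """Random small spike train + factorized kernel (shared by oracle tests)."""
    from snnwm import FactorizedDelayKernel, SpikeTrain

    Ni = int(rng.integers(1, max_dim + 1))
    Nj = int(rng.integers(1, max_dim + 1))
    Nk = int(rng.integers(1, max_dim + 1))
    T = int(rng.integers(Nk, max_T + 1))
    S = SpikeTrain((rng.random((T, Ni)) < 0.4).astype(float))
    kernel = FactorizedDelayKernel(
        W1=rng.normal(size=(Ni, Nj)),
        w2=rng.normal(size=Nk),
        delays=np.sort(rng.choice(T, size=Nk, replace=False)),
    )
    return S, kernel
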