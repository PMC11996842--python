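import numpy as np
import pytest

from qcogsim.fixtures import FixtureSpec, generate_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_state(dim: int, seed: int):
    return generate_fixture(FixtureSpec(dim=dim, seed=seed, kind="state"))


def random_hermitian(dim: int, seed: int, scale: float = 1.0):
    return generate_fixture(
        FixtureSpec(dim=dim, seed=seed, kind="hermitian", scale=scale)
    )


def random_psd(dim: int, seed: int, scale: float = 1.0):
    return generate_fixture(FixtureSpec(dim=dim, seed=seed, kind="psd", scale=scale))
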