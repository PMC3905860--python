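import numpy as np
import pytest

from hdnakit import build_surrogate_map


@pytest.fixture(scope="session")
def hdna_map():
    return build_surrogate_map("hdna", seed=11)


@pytest.fixture(scope="session")
def control_map():
    return build_surrogate_map("control", seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))
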