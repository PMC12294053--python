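import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def random_seq():
    def make(length: int, seed: int = 0) -> str:
        r = np.random.default_rng(seed)
        return "".join("ACGT"[i] for i in r.integers(0, 4, size=length))

    return make
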