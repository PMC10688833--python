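import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, length)])


def mutate_seq(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    out = list(seq)
    for p in rng.choice(len(seq), size=n_subs, replace=False):
        out[p] = "ACGT"[("ACGT".index(out[p]) + 1 + rng.integers(0, 3)) % 4]
    return "".join(out)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230615)
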