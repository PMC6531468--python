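import numpy as np
import pytest

from selexgram.seqio import PoolManifest
from selexgram.simulate import make_fixture_101mers

BASES = "ACGU"


def random_tags(rng: np.random.Generator, n: int, length: int = 40) -> list[str]:
    return ["".join(BASES[b] for b in row) for row in rng.integers(0, 4, (n, length))]


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[b] for b in rng.integers(0, 4, length))


@pytest.fixture(scope="session")
def fixtures_101():
    return make_fixture_101mers()


@pytest.fixture()
def manifest():
    return PoolManifest(
        samples={"S1": "ACGU", "S2": "GUCA"},
        adapters=("GGGAGA", "UCCUCA"),
        umi_length=5,
        length_bounds=(38, 40),
    )


@pytest.fixture()
def manifest_no_umi():
    return PoolManifest(
        samples={"S1": "ACGU"},
        adapters=("GGGAGA", "UCCUCA"),
        umi_length=0,
        length_bounds=(38, 40),
    )
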