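import random

import pytest

from ggyl.fixtures import FixtureSpec, generate_toolkit, generate_xylose_demo


@pytest.fixture(scope="session")
def toolkit():
    """The default 64-brick synthetic kit (seed 42)."""
    return generate_toolkit(FixtureSpec(seed=42))


@pytest.fixture(scope="session")
def demo():
    """Xylose-pathway demo: kit + 3 mock pathway genes + 3-TU design."""
    return generate_xylose_demo(seed=42)


@pytest.fixture()
def rng():
    return random.Random(20190531)


def random_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))
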