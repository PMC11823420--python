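import numpy as np
import pytest

from tavmd.cgmodel import Conformation, ToyForceField, generate_random_chain


@pytest.fixture(scope="session")
def ff():
    return ToyForceField()


@pytest.fixture(scope="session")
def chain12(ff):
    """A small random chain used across geometry tests."""
    return generate_random_chain(12, seed=5, ff=ff)


@pytest.fixture(scope="session")
def chain25(ff):
    return generate_random_chain(25, seed=1, ff=ff)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250923)


def perturbed(conf: Conformation, scale: float, seed: int) -> Conformation:
    """Randomly displaced copy (keeps bonded beads apart at small scale)."""
    r = np.random.default_rng(seed)
    return Conformation(conf.coords + scale * r.normal(size=conf.coords.shape))
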