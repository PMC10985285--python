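import numpy as np
import pytest

from degenmhc.pseudoseq import ContactAssignment
from degenmhc.synthetic import make_world


@pytest.fixture(scope="session")
def world():
    return make_world(7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_assignment():
    return ContactAssignment({7: frozenset({2}), 9: frozenset({2, 3}), 24: frozenset({5})})


def random_assignment(rng: np.random.Generator, n_positions: int = 6) -> ContactAssignment:
    positions = sorted(rng.choice(np.arange(1, 40), size=n_positions, replace=False).tolist())
    contacts = {}
    for p in positions:
        k = int(rng.integers(1, 4))
        cores = frozenset(rng.choice(np.arange(1, 10), size=k, replace=False).tolist())
        contacts[int(p)] = cores
    return ContactAssignment(contacts)
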