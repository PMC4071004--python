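import numpy as np
import pytest

from timecarry import (
    ObserverParams,
    generate_sequence,
    make_duration_set,
    make_guide,
    simulate_session,
)


@pytest.fixture(scope="session")
def duration_set():
    return make_duration_set(300, 900, 7)


@pytest.fixture(scope="session")
def default_sequence(duration_set):
    n = len(duration_set.labels) ** 2 * 8
    guide = make_guide(n, seed=1)
    return generate_sequence(duration_set, 8, guide, seed=1)


@pytest.fixture(scope="session")
def small_sequence(duration_set):
    n = len(duration_set.labels) ** 2 * 2
    guide = make_guide(n, seed=3)
    return generate_sequence(duration_set, 2, guide, seed=3)


@pytest.fixture(scope="session")
def default_session(default_sequence):
    return simulate_session(
        default_sequence, ObserverParams(M=13, theta=49.0, cv=0.16, seed=2)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
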