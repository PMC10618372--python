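import numpy as np
import pytest

from pvntherm import markov_core as mc


@pytest.fixture(scope="session")
def two_state():
    """C <-> O with opening 2/ms (closed tau 0.5 ms), closing 0.5/ms."""
    return mc.linear_chain_scheme([2.0], [0.5])


@pytest.fixture(scope="session")
def scheme22():
    return mc.trpv4_scheme(22.0)


@pytest.fixture(scope="session")
def scheme37():
    return mc.trpv4_scheme(37.0)


def random_tree_scheme(rng: np.random.Generator, max_states: int = 6) -> mc.KineticScheme:
    """Random irreducible scheme on a tree topology.

    Trees make the chain reversible, so within-class sub-generators are
    symmetrizable and dwell distributions are real exponential mixtures.
    """
    n = int(rng.integers(2, max_states + 1))
    while True:
        classes = rng.integers(0, 2, size=n)
        if 0 < classes.sum() < n:
            break
    off = np.zeros((n, n))
    for i in range(1, n):  # random tree: attach each node to an earlier one
        j = int(rng.integers(0, i))
        off[i, j] = rng.uniform(0.05, 5.0)
        off[j, i] = rng.uniform(0.05, 5.0)
    ids = tuple(f"S{i}" for i in range(n))
    return mc.KineticScheme(
        state_ids=ids,
        class_of_state=tuple("open" if c else "closed" for c in classes),
        rates=off - np.diag(off.sum(axis=1)),
    )


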