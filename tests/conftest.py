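import itertools

import numpy as np
import pytest

from methylising.ising import RegionModel


def enumerate_states(model: RegionModel):
    """Brute-force oracle: all 2^R states with exact probabilities, computed
    directly from the energy definition (independent of the chain code)."""
    R = model.n_sites
    states = list(itertools.product([0, 1], repeat=R))
    weights = []
    for x in states:
        s = [2 * xi - 1 for xi in x]
        e = sum(float(a) * si for a, si in zip(model.a, s))
        e += sum(float(c) * s[i + 1] * s[i] for i, c in enumerate(model.c))
        weights.append(np.exp(e))
    Z = float(sum(weights))
    return states, np.array(weights) / Z, Z


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def random_small_model(rng):
    def make(R=None):
        R = R or int(rng.integers(2, 9))
        return RegionModel(a=rng.normal(0, 1.5, R), c=rng.normal(0, 1.5, R - 1))

    return make
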