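import numpy as np
import pytest

from openchain import make_chain


def random_open_chain(rng: np.random.Generator, S: int, max_row_sum: float = 0.95):
    """Random strictly sub-stochastic chain: nonnegative rows scaled to
    row sums drawn in (0.2, max_row_sum)."""
    W = rng.random((S, S))
    sums = rng.uniform(0.2, max_row_sum, size=S)
    Q = W / W.sum(axis=1, keepdims=True) * sums[:, None]
    return make_chain(Q)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def random_chain_factory():
    return random_open_chain
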