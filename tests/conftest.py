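import numpy as np
import pytest

from asteria.design import DesignMatrix, expand_interactions


@pytest.fixture
def tiny_design():
    """8 experiments x 3 modifications, handcrafted, no redundancy."""
    L = np.array(
        [
            [1, 1, 0],
            [1, 0, 0],
            [0, 1, 0],
            [0, 0, 1],
            [1, 1, 1],
            [0, 1, 1],
            [1, 0, 1],
            [0, 0, 0],
        ]
    )
    return DesignMatrix(L, [f"N{i}" for i in range(8)], ["A", "B", "C"])


@pytest.fixture
def expanded(tiny_design):
    return expand_interactions(tiny_design)


def random_design(n, q, seed, p=0.5):
    """Seeded Bernoulli design, redrawn until columns are non-degenerate."""
    rng = np.random.default_rng(seed)
    while True:
        L = (rng.random((n, q)) < p).astype(int)
        sums = L.sum(axis=0)
        if (sums > 0).all() and (sums < n).all():
            if len({L[:, j].tobytes() for j in range(q)}) == q:
                return DesignMatrix(
                    L, [f"N{i}" for i in range(n)], [f"M{j+1}" for j in range(q)]
                )
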