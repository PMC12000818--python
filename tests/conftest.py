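import numpy as np
import pytest

from gromm import (
    DirichletParams,
    Grouping,
    ItemDomain,
    ItemProbTables,
    paper_scenario,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def tiny_tables():
    """Two binary items, K=3 (the d_j < K regime of the Khatri-Rao examples)."""
    a = np.array([0.1, 0.5, 0.9])
    b = np.array([0.2, 0.4, 0.8])
    return ItemProbTables([np.vstack([a, 1 - a]), np.vstack([b, 1 - b])])


@pytest.fixture
def small_model():
    """p=4 binary items in G=2 groups with K=2 profiles — brute-forceable."""
    t = np.array([[0.8, 0.3], [0.2, 0.7]])
    t2 = np.array([[0.6, 0.1], [0.4, 0.9]])
    return dict(
        grouping=Grouping([0, 0, 1, 1], 2),
        tables=ItemProbTables([t, t2, t, t2]),
        alpha=DirichletParams([0.4, 0.5]),
        domain=ItemDomain([2, 2, 2, 2]),
    )


@pytest.fixture(scope="session")
def scenario_k3():
    return paper_scenario(3, 30, 6)
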