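"""Seeded simulation from the dimension-grouped generative process.

Also constructs the benchmark ground-truth scenarios used throughout the
test-bed: three-category items arranged in ``p/G`` stacked copies of the
identity grouping, conditional probability tables cycling through six fixed
``3 x 4`` blocks, and small Dirichlet concentrations
(``0.4, 0.5[, 0.6[, 0.7]]``) so that membership vectors are typically
dominated by one profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model_core import (
    AssignmentMatrix,
    DirichletParams,
    Grouping,
    ItemDomain,
    ItemProbTables,
    MembershipMatrix,
    ResponseMatrix,
)

__all__ = [
    "TruthScenario",
    "SimulatedDataset",
    "paper_scenario",
    "scenario_name",
    "sample_dataset",
    "SCENARIO_TABLE_BLOCKS",
    "SCENARIO_ALPHAS",
    "SCENARIO_SHAPES",
]

# Six 3x4 conditional probability tables (rows = categories, columns =
# extreme profiles) cycled over the items; every column sums to one.
SCENARIO_TABLE_BLOCKS: tuple[np.ndarray, ...] = tuple(
    np.array(block, dtype=float)
    for block in (
        [[0.1, 0.7, 0.3, 0.1],
         [0.8, 0.2, 0.4, 0.1],
         [0.1, 0.1, 0.3, 0.8]],
        [[0.1, 0.8, 0.1, 0.2],
         [0.2, 0.1, 0.6, 0.5],
         [0.7, 0.1, 0.3, 0.3]],
        [[0.1, 0.8, 0.2, 0.9],
         [0.2, 0.1, 0.5, 0.05],
         [0.7, 0.1, 0.3, 0.05]],
        [[0.1, 0.1, 0.8, 0.3],
         [0.8, 0.2, 0.1, 0.6],
         [0.1, 0.7, 0.1, 0.1]],
        [[0.2, 0.7, 0.3, 0.1],
         [0.6, 0.2, 0.4, 0.1],
         [0.2, 0.1, 0.3, 0.8]],
        [[0.1, 0.8, 0.1, 0.2],
         [0.2, 0.1, 0.1, 0.6],
         [0.7, 0.1, 0.8, 0.2]],
    )
)

#: true Dirichlet concentrations per profile count
SCENARIO_ALPHAS = {
    2: (0.4, 0.5),
    3: (0.4, 0.5, 0.6),
    4: (0.4, 0.5, 0.6, 0.7),
}

#: supported (p, G) shapes; p/G identity blocks stack into the grouping
SCENARIO_SHAPES = ((30, 6), (60, 12), (90, 15))


@dataclass(frozen=True)
class TruthScenario:
    """A complete ground-truth parameter set for simulation studies."""

    grouping: Grouping
    tables: ItemProbTables
    alpha: DirichletParams
    tag: str = "custom"

    def __post_init__(self):
        if self.grouping.p != self.tables.p:
            raise ValueError("grouping and tables disagree on item count")
        if self.alpha.K != self.tables.K:
            raise ValueError("alpha and tables disagree on profile count")

    @property
    def domain(self) -> ItemDomain:
        return self.tables.domain

    @property
    def K(self) -> int:
        return self.tables.K

    @property
    def G(self) -> int:
        return self.grouping.G

    @property
    def p(self) -> int:
        return self.grouping.p


@dataclass(frozen=True)
class SimulatedDataset:
    """Responses plus the latent draws that generated them."""

    responses: ResponseMatrix
    memberships: MembershipMatrix
    assignments: AssignmentMatrix
    seed: int
    truth: TruthScenario


def scenario_name(K: int, p: int, G: int) -> str:
    return f"K{K}_p{p}_G{G}"


def paper_scenario(K: int, p: int = 30, G: int = 6) -> TruthScenario:
    """Benchmark truth with ``d_j = 3`` items and cycled table blocks.

    The six fixed ``3 x 4`` blocks are cycled over the items; for ``K < 4``
    the leading ``K`` columns of each block are retained (each column is
    already a probability distribution, so no renormalization is needed).
    The grouping stacks ``p/G`` copies of the identity, i.e.
    ``s_j = j mod G``, and the concentrations are the fixed per-``K``
    vectors.  Supported shapes: ``(p, G)`` in ``{(30, 6), (60, 12),
    (90, 15)}`` with ``K`` in ``{2, 3, 4}``.
    """
    if (p, G) not in SCENARIO_SHAPES:
        raise ValueError(f"unsupported (p, G) = ({p}, {G}); "
                         f"supported: {SCENARIO_SHAPES}")
    if K not in SCENARIO_ALPHAS:
        raise ValueError(f"unsupported K = {K}; supported: 2, 3, 4")
    tables = [SCENARIO_TABLE_BLOCKS[j % 6][:, :K] for j in range(p)]
    s = np.arange(p) % G
    return TruthScenario(
        grouping=Grouping(s, G),
        tables=ItemProbTables(tables),
        alpha=DirichletParams(SCENARIO_ALPHAS[K]),
        tag=scenario_name(K, p, G),
    )


def sample_dataset(truth: TruthScenario, n: int, seed: int) -> SimulatedDataset:
    """Draw ``n`` subjects from the generative process.

    ``pi_i ~ Dirichlet(alpha)`` i.i.d., ``z_{i,g} | pi_i ~ Categorical(pi_i)``
    per group, and ``y_{i,j} | z_{i,s_j} = k ~ Categorical(Lambda_j[:, k])``.
    The three sampling stages draw from independent substreams spawned from
    the master seed, each consuming draws in subject order, so enlarging
    ``n`` with the same seed extends the dataset instead of reshuffling it.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    pi_rng, z_rng, y_rng = (np.random.default_rng(c) for c in ss.spawn(3))
    p, G, K = truth.p, truth.G, truth.K

    # Dirichlet via normalized gammas, one subject at a time for prefix
    # stability of the stream.
    gam = pi_rng.standard_gamma(np.tile(truth.alpha.alpha, (n, 1)))
    pi = gam / gam.sum(axis=1, keepdims=True)

    u = z_rng.random((n, G))
    cdf = np.cumsum(pi, axis=1)
    z = (u[:, :, None] > cdf[:, None, :]).sum(axis=2)

    u_y = y_rng.random((n, p))
    y = np.empty((n, p), dtype=np.int64)
    s = truth.grouping.s
    for j in range(p):
        table_cdf = np.cumsum(truth.tables[j], axis=0)  # d_j x K
        zk = z[:, s[j]]
        y[:, j] = (u_y[:, j, None] > table_cdf.T[zk, :]).sum(axis=1)

    return SimulatedDataset(
        responses=ResponseMatrix(y, truth.domain),
        memberships=MembershipMatrix(pi),
        assignments=AssignmentMatrix(z, K),
        seed=int(seed),
        truth=truth,
    )
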