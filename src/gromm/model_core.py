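"""Core probability structure of the dimension-grouped mixed membership model.

The model describes ``n`` subjects answering ``p`` categorical items (item
``j`` has ``d_j`` unordered categories).  Items are partitioned into ``G``
groups.  Each subject ``i`` owns a membership vector ``pi_i`` on the
``(K-1)``-simplex over ``K`` extreme latent profiles; for every group ``g``
the subject draws one profile realization ``z_{i,g} ~ Categorical(pi_i)``,
shared by all items in that group, and then answers item ``j`` (in group
``g``) from column ``z_{i,g}`` of its ``d_j x K`` conditional probability
table ``Lambda_j``.

Marginalizing the memberships under a ``Dirichlet(alpha)`` law yields a
hybrid CP/Tucker decomposition of the ``p``-way contingency probability
tensor whose ``G``-mode core holds the Dirichlet product moments
``E[pi_{k_1} ... pi_{k_G}]``.  This module houses the parameter containers
and evaluates that probability structure: conditional and marginal pmfs,
the core tensor, Khatri-Rao products, and two-item marginals.

Categories and group labels are 0-based throughout the in-memory API; the
file boundary (``gromm.io_cli``) converts to and from the 1-based coding
used in data files.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import khatri_rao as _scipy_khatri_rao
from scipy.special import logsumexp, poch

__all__ = [
    "ItemDomain",
    "Grouping",
    "ItemProbTables",
    "DirichletParams",
    "MembershipMatrix",
    "AssignmentMatrix",
    "CoreTensor",
    "ResponseMatrix",
    "khatri_rao",
    "dirichlet_product_moment",
    "core_tensor",
    "pmf_given_membership",
    "log_pmf_given_membership",
    "marginal_pmf",
    "pairwise_marginal",
]

#: refuse to materialize a core tensor with more entries than this
CORE_TENSOR_ENTRY_CAP = 10_000_000

#: tolerance for simplex/column-sum invariants on construction
_SIMPLEX_TOL = 1e-10
#: deviations below this are silently renormalized; larger ones are rejected
_RENORM_TOL = 1e-6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ItemDomain:
    """Number of items ``p`` and per-item category counts ``d_j >= 2``."""

    d: tuple[int, ...]

    def __init__(self, d: Sequence[int]):
        d = tuple(int(x) for x in d)
        if len(d) == 0:
            raise ValueError("need at least one item")
        if any(x < 2 for x in d):
            raise ValueError(f"every item needs >= 2 categories, got {d}")
        object.__setattr__(self, "d", d)

    @property
    def p(self) -> int:
        return len(self.d)

    @property
    def d_max(self) -> int:
        return max(self.d)


@dataclass(frozen=True)
class Grouping:
    """Assignment of ``p`` items to ``G`` groups (0-based labels).

    ``s[j] = g`` means item ``j`` belongs to group ``g``.  The equivalent
    binary ``p x G`` matrix form ``L`` has exactly one 1 per row.
    """

    s: np.ndarray
    G: int

    def __init__(self, s: Sequence[int], G: int):
        s = np.asarray(s, dtype=np.int64)
        if s.ndim != 1:
            raise ValueError("s must be a 1-d label sequence")
        G = int(G)
        if G < 1:
            raise ValueError("G must be >= 1")
        if s.size and (s.min() < 0 or s.max() >= G):
            raise ValueError(f"group labels must lie in [0, {G}), got range "
                             f"[{s.min()}, {s.max()}]")
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "G", G)
        s.flags.writeable = False

    @property
    def p(self) -> int:
        return self.s.size

    def to_matrix(self) -> np.ndarray:
        """Binary ``p x G`` grouping matrix ``L``."""
        L = np.zeros((self.p, self.G), dtype=np.int64)
        L[np.arange(self.p), self.s] = 1
        return L

    @classmethod
    def from_matrix(cls, L: np.ndarray) -> "Grouping":
        L = np.asarray(L)
        if L.ndim != 2 or not np.all(L.sum(axis=1) == 1) or not np.isin(L, (0, 1)).all():
            raise ValueError("L must be binary with exactly one 1 per row")
        return cls(np.argmax(L, axis=1), L.shape[1])

    def items_in(self, g: int) -> np.ndarray:
        return np.flatnonzero(self.s == g)


@dataclass(frozen=True)
class ItemProbTables:
    """Per-item ``d_j x K`` conditional probability tables.

    Column ``k`` of table ``j`` is the distribution of item ``j``'s response
    under extreme profile ``k``; every column must sum to one.  Columns that
    deviate from unit sum by less than ``1e-6`` are renormalized, larger
    deviations are rejected.
    """

    tables: tuple[np.ndarray, ...]
    K: int

    def __init__(self, tables: Sequence[np.ndarray]):
        if len(tables) == 0:
            raise ValueError("need at least one table")
        fixed = []
        K = np.asarray(tables[0]).shape[1]
        for j, t in enumerate(tables):
            t = np.array(t, dtype=float)
            if t.ndim != 2:
                raise ValueError(f"table {j} is not a matrix")
            if t.shape[1] != K:
                raise ValueError(f"table {j} has {t.shape[1]} columns, expected K={K}")
            if t.shape[0] < 2:
                raise ValueError(f"table {j} needs >= 2 categories")
            if (t < -_SIMPLEX_TOL).any() or (t > 1 + _SIMPLEX_TOL).any():
                raise ValueError(f"table {j} has entries outside [0, 1]")
            colsum = t.sum(axis=0)
            dev = np.abs(colsum - 1.0).max()
            if dev > _RENORM_TOL:
                raise ValueError(
                    f"table {j} columns sum to {colsum} (max deviation {dev:.2e}); "
                    "columns must be probability distributions")
            if dev > _SIMPLEX_TOL:
                t = t / colsum
            t.flags.writeable = False
            fixed.append(t)
        object.__setattr__(self, "tables", tuple(fixed))
        object.__setattr__(self, "K", int(K))

    @property
    def p(self) -> int:
        return len(self.tables)

    @property
    def domain(self) -> ItemDomain:
        return ItemDomain([t.shape[0] for t in self.tables])

    def __getitem__(self, j: int) -> np.ndarray:
        return self.tables[j]

    def stacked(self) -> np.ndarray:
        """All tables stacked vertically into a ``(sum_j d_j) x K`` matrix."""
        return np.vstack(self.tables)


@dataclass(frozen=True)
class DirichletParams:
    """Concentration vector ``alpha`` of the Dirichlet membership law."""

    alpha: np.ndarray

    def __init__(self, alpha: Sequence[float]):
        alpha = np.asarray(alpha, dtype=float)
        if alpha.ndim != 1 or alpha.size < 1:
            raise ValueError("alpha must be a non-empty vector")
        if not (alpha > 0).all():
            raise ValueError(f"all concentrations must be positive, got {alpha}")
        alpha = alpha.copy()
        alpha.flags.writeable = False
        object.__setattr__(self, "alpha", alpha)

    @property
    def K(self) -> int:
        return self.alpha.size

    @property
    def alpha0(self) -> float:
        """Total concentration ``alpha_0 = sum_k alpha_k``."""
        return float(self.alpha.sum())

    @property
    def mean(self) -> np.ndarray:
        """Dirichlet mean ``eta = alpha / alpha_0``."""
        return self.alpha / self.alpha0


@dataclass(frozen=True)
class MembershipMatrix:
    """``n x K`` matrix whose rows are membership vectors on the simplex."""

    pi: np.ndarray

    def __init__(self, pi: np.ndarray):
        pi = np.array(pi, dtype=float)
        if pi.ndim != 2:
            raise ValueError("pi must be an n x K matrix")
        if (pi < -_SIMPLEX_TOL).any():
            raise ValueError("membership weights must be nonnegative")
        if np.abs(pi.sum(axis=1) - 1.0).max() > _SIMPLEX_TOL:
            raise ValueError("membership rows must sum to 1")
        pi.flags.writeable = False
        object.__setattr__(self, "pi", pi)

    @property
    def n(self) -> int:
        return self.pi.shape[0]

    @property
    def K(self) -> int:
        return self.pi.shape[1]


@dataclass(frozen=True)
class AssignmentMatrix:
    """``n x G`` matrix of per-group profile realizations in ``[0, K)``."""

    z: np.ndarray
    K: int

    def __init__(self, z: np.ndarray, K: int):
        z = np.array(z, dtype=np.int64)
        if z.ndim != 2:
            raise ValueError("z must be an n x G matrix")
        K = int(K)
        if z.size and (z.min() < 0 or z.max() >= K):
            raise ValueError(f"assignments must lie in [0, {K})")
        z.flags.writeable = False
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "K", K)

    @property
    def n(self) -> int:
        return self.z.shape[0]

    @property
    def G(self) -> int:
        return self.z.shape[1]

    def multiplicities(self) -> np.ndarray:
        """``n x K`` counts ``Z_ik = #{g : z_{i,g} = k}`` (rows sum to G)."""
        out = np.zeros((self.n, self.K), dtype=np.int64)
        for g in range(self.G):
            np.add.at(out, (np.arange(self.n), self.z[:, g]), 1)
        return out


@dataclass(frozen=True)
class CoreTensor:
    """``G``-mode tensor of Dirichlet product moments, entries sum to one."""

    phi: np.ndarray

    def __init__(self, phi: np.ndarray):
        phi = np.array(phi, dtype=float)
        if phi.ndim < 1 or len(set(phi.shape)) != 1:
            raise ValueError("phi must have identical mode dimensions")
        if (phi < 0).any():
            raise ValueError("core tensor entries must be nonnegative")
        if abs(phi.sum() - 1.0) > 1e-8:
            raise ValueError(f"core tensor entries sum to {phi.sum()}, expected 1")
        phi.flags.writeable = False
        object.__setattr__(self, "phi", phi)

    @property
    def G(self) -> int:
        return self.phi.ndim

    @property
    def K(self) -> int:
        return self.phi.shape[0]


@dataclass(frozen=True)
class ResponseMatrix:
    """``n x p`` table of 0-based categorical responses with its item domain."""

    y: np.ndarray
    domain: ItemDomain

    def __init__(self, y: np.ndarray, domain: ItemDomain):
        y = np.array(y, dtype=np.int64)
        if y.ndim != 2:
            raise ValueError("y must be an n x p matrix")
        if y.shape[1] != domain.p:
            raise ValueError(f"y has {y.shape[1]} columns, domain has p={domain.p}")
        d = np.asarray(domain.d)
        if y.size and ((y < 0).any() or (y >= d[None, :]).any()):
            bad = np.argwhere((y < 0) | (y >= d[None, :]))[0]
            raise ValueError(
                f"response out of range at row {bad[0]}, item {bad[1]}: "
                f"value {y[bad[0], bad[1]]} not in [0, {d[bad[1]]})")
        y.flags.writeable = False
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "domain", domain)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.y.shape[1]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def khatri_rao(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker product of two matrices with equal column count.

    Column ``k`` of the result is ``kron(A[:, k], B[:, k])``; the output has
    shape ``(m*s) x K`` for inputs ``m x K`` and ``s x K``.  Chaining the
    product over the items of a partition set builds the stacked conditional
    tables whose column rank drives the identifiability conditions.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"column counts differ: {A.shape[1]} vs {B.shape[1]}")
    return _scipy_khatri_rao(A, B)


def khatri_rao_chain(mats: Sequence[np.ndarray]) -> np.ndarray:
    """Left-fold of :func:`khatri_rao` over a non-empty sequence of matrices."""
    mats = list(mats)
    if not mats:
        raise ValueError("need at least one matrix")
    out = np.atleast_2d(np.asarray(mats[0], dtype=float))
    for m in mats[1:]:
        out = khatri_rao(out, m)
    return out


def dirichlet_product_moment(alpha: DirichletParams, m: Sequence[int]) -> float:
    """Moment ``E[prod_k pi_k^{m_k}]`` under ``pi ~ Dirichlet(alpha)``.

    Uses the rising-factorial closed form

        ``prod_k alpha_k^{(m_k)} / alpha_0^{(M)}``,  ``M = sum_k m_k``,

    where ``x^{(m)} = x (x+1) ... (x+m-1)``.  With ``M = G`` these moments
    are the entries of the hybrid-decomposition core tensor.
    """
    m = np.asarray(m, dtype=np.int64)
    if m.shape != (alpha.K,):
        raise ValueError(f"multiplicity vector must have length K={alpha.K}")
    if (m < 0).any():
        raise ValueError("multiplicities must be nonnegative")
    num = np.prod(poch(alpha.alpha, m))
    den = poch(alpha.alpha0, int(m.sum()))
    return float(num / den)


def core_tensor(alpha: DirichletParams, G: int,
                entry_cap: int = CORE_TENSOR_ENTRY_CAP) -> CoreTensor:
    """Core tensor of the hybrid decomposition for ``G`` groups.

    Entry ``(k_1, ..., k_G)`` equals ``E[pi_{k_1} ... pi_{k_G}]`` under
    ``Dirichlet(alpha)``; the ``K^G`` entries sum to one.  Tensors larger
    than ``entry_cap`` entries are refused — use the per-subject
    latent-variable likelihood (:func:`pmf_given_membership`) instead of
    materializing the core.
    """
    G = int(G)
    if G < 1:
        raise ValueError("G must be >= 1")
    K = alpha.K
    n_entries = K ** G
    if n_entries > entry_cap:
        raise MemoryError(
            f"core tensor would have K^G = {K}^{G} = {n_entries} entries "
            f"(cap {entry_cap}); evaluate the likelihood per subject via "
            "pmf_given_membership instead")
    a = alpha.alpha
    # phi over index tuples = prod over positions of (alpha_k + #prior uses of k),
    # normalized by alpha_0^(G); built mode by mode in log space would be
    # overkill — the Polya-urn recursion below is exact and vectorized.
    phi = a / alpha.alpha0
    counts = np.eye(K, dtype=float)  # counts[tuple..., k] usage multiplicities
    for g in range(1, G):
        # phi has shape (K,)*g, counts has shape (K,)*g + (K,)
        step = (counts + a) / (alpha.alpha0 + g)
        phi = phi[..., None] * step
        counts = counts[..., None, :] + np.eye(K)[(None,) * g]
    return CoreTensor(phi)


def log_pmf_given_membership(y_i: np.ndarray, grouping: Grouping,
                             tables: ItemProbTables, pi_i: np.ndarray) -> float:
    """Log-probability of one response vector given its membership weights.

    Evaluates ``sum_g log sum_k pi_{i,k} prod_{j: s_j = g} lambda_{j, y_j, k}``
    with a log-sum-exp per group; a category impossible under every profile
    in some group yields ``-inf`` rather than an exception.
    """
    y_i = np.asarray(y_i, dtype=np.int64)
    pi_i = np.asarray(pi_i, dtype=float)
    if y_i.shape != (tables.p,) or pi_i.shape != (tables.K,):
        raise ValueError("inputs dimensionally inconsistent")
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi_i)
        # per-group accumulators of log pi_k + sum_j log lambda_{j, y_j, k}
        acc = np.tile(log_pi, (grouping.G, 1))
        for j in range(tables.p):
            acc[grouping.s[j]] += np.log(tables[j][y_i[j], :])
    total = 0.0
    for g in range(grouping.G):
        row = acc[g]
        if np.all(np.isneginf(row)):
            return float("-inf")
        total += logsumexp(row)
    return float(total)


def pmf_given_membership(y_i: np.ndarray, grouping: Grouping,
                         tables: ItemProbTables, pi_i: np.ndarray) -> float:
    """Probability of one response vector given membership weights ``pi_i``."""
    return float(np.exp(log_pmf_given_membership(y_i, grouping, tables, pi_i)))


def marginal_pmf(y_i: np.ndarray, grouping: Grouping, tables: ItemProbTables,
                 alpha: DirichletParams,
                 entry_cap: int = CORE_TENSOR_ENTRY_CAP) -> float:
    """Marginal probability of a response vector with memberships integrated out.

    Contracts the core tensor against the per-group profile likelihoods:
    ``sum_{k_1..k_G} prod_g prod_{j: s_j=g} lambda_{j, y_j, k_g} *
    phi_{k_1..k_G}``.  Requires ``K^G`` within the core-tensor cap.
    """
    y_i = np.asarray(y_i, dtype=np.int64)
    if y_i.shape != (tables.p,):
        raise ValueError("response vector has wrong length")
    phi = core_tensor(alpha, grouping.G, entry_cap=entry_cap).phi
    # M[g, k] = prod_{j in group g} lambda_{j, y_j, k}
    M = np.ones((grouping.G, tables.K))
    for j in range(tables.p):
        M[grouping.s[j]] *= tables[j][y_i[j], :]
    out = phi
    for g in range(grouping.G):
        out = np.tensordot(M[g], out, axes=([0], [0]))
    return float(out)


def pairwise_marginal(j: int, j2: int, grouping: Grouping,
                      tables: ItemProbTables,
                      alpha: DirichletParams) -> np.ndarray:
    """Joint ``d_j x d_j2`` probability table of two items under the model.

    Items sharing a group see the same profile realization, so
    ``P(c, c') = sum_k eta_k lambda_{j,c,k} lambda_{j2,c',k}``; items in
    different groups couple only through the second-order Dirichlet moments
    ``E[pi_k pi_{k'}]``.
    """
    if j == j2:
        raise ValueError("the two items must differ")
    Lj, Lj2 = tables[j], tables[j2]
    if grouping.s[j] == grouping.s[j2]:
        W = np.diag(alpha.mean)
    else:
        a, a0 = alpha.alpha, alpha.alpha0
        W = np.outer(a, a) / (a0 * (a0 + 1.0))
        W[np.diag_indices_from(W)] = a * (a + 1.0) / (a0 * (a0 + 1.0))
    return Lj @ W @ Lj2.T


def enumerate_support(domain: ItemDomain):
    """Iterate over all response patterns of a (small) item domain."""
    return (np.array(c, dtype=np.int64)
            for c in itertools.product(*[range(dj) for dj in domain.d]))
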