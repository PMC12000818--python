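"""Posterior summaries: grouping mode, profile alignment, accuracy metrics,
WAIC and latent-dimension selection, and Cramér's V association diagnostics.

The sampler imposes no ordering on the extreme profiles, so draws from
different chains (or a chain and the truth) may be related by a column
permutation of every table plus the matching permutation of ``alpha``.
:func:`align_profiles` recovers that permutation by matching columns of the
stacked table matrices through their inner products, repairing argmax
collisions greedily to a bijection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.metrics import adjusted_rand_score

from .mcmc import MCMCConfig, PosteriorSamples, run_chain
from .model_core import (
    DirichletParams,
    Grouping,
    ItemProbTables,
    ResponseMatrix,
    pairwise_marginal,
)

__all__ = [
    "FitSummary",
    "grouping_posterior_mode",
    "align_profiles",
    "apply_permutation",
    "parameter_rmse",
    "adjusted_rand_index",
    "waic",
    "summarize_fit",
    "select_dimensions",
    "SelectionResult",
    "cramers_v_sample",
    "cramers_v_model",
]


@dataclass(frozen=True)
class FitSummary:
    """Point estimates and fit criteria extracted from one posterior run."""

    grouping: Grouping
    mean_tables: ItemProbTables
    mean_alpha: np.ndarray
    permutation: Optional[np.ndarray]
    waic: float
    lppd: float
    p_waic2: float
    has_empty_group: bool


def grouping_posterior_mode(s_draws: np.ndarray, G: int) -> Grouping:
    """Per-item majority group label across retained draws.

    Ties break toward the smallest group index.  ``s_draws`` is ``T x p``
    with 0-based labels.
    """
    s_draws = np.asarray(s_draws, dtype=np.int64)
    if s_draws.ndim != 2 or s_draws.shape[0] == 0:
        raise ValueError("need a non-empty T x p array of grouping draws")
    p = s_draws.shape[1]
    mode = np.empty(p, dtype=np.int64)
    for j in range(p):
        counts = np.bincount(s_draws[:, j], minlength=G)
        mode[j] = int(np.argmax(counts))  # argmax takes the first maximum
    return Grouping(mode, G)


def align_profiles(est_tables: ItemProbTables,
                   ref_tables: ItemProbTables) -> np.ndarray:
    """Permutation matching estimated profiles to reference profiles.

    Stacks each table set into a ``(sum_j d_j) x K`` matrix, forms the inner
    product matrix ``ref_mat.T @ est_mat`` and takes the argmax of each row
    ``k`` as the estimated column ``i_k`` matching reference profile ``k``.
    Collisions (two rows sharing an argmax) are repaired by assigning
    (row, column) pairs greedily in decreasing inner-product order, which
    always yields a bijection.  Returns ``perm`` with ``perm[k] = i_k``;
    apply as ``est[:, perm]`` to compare against the reference order.
    """
    R = ref_tables.stacked()
    E = est_tables.stacked()
    if R.shape != E.shape:
        raise ValueError(f"stacked shapes differ: {R.shape} vs {E.shape}")
    K = R.shape[1]
    ip = R.T @ E
    perm = np.argmax(ip, axis=1)
    if len(set(perm.tolist())) == K:
        return perm
    # collision repair: greedy assignment on decreasing inner products
    perm = np.full(K, -1, dtype=np.int64)
    order = np.dstack(np.unravel_index(np.argsort(ip, axis=None)[::-1],
                                       ip.shape))[0]
    used_rows: set[int] = set()
    used_cols: set[int] = set()
    for r, c in order:
        if r not in used_rows and c not in used_cols:
            perm[r] = c
            used_rows.add(int(r))
            used_cols.add(int(c))
        if len(used_rows) == K:
            break
    return perm


def apply_permutation(tables: ItemProbTables, alpha: np.ndarray,
                      perm: np.ndarray) -> tuple[ItemProbTables, np.ndarray]:
    """Reorder profile columns of every table and the alpha vector."""
    perm = np.asarray(perm, dtype=np.int64)
    return (ItemProbTables([t[:, perm] for t in tables.tables]),
            np.asarray(alpha, dtype=float)[perm])


def parameter_rmse(est_tables: ItemProbTables, ref_tables: ItemProbTables,
                   est_alpha: np.ndarray, ref_alpha: np.ndarray,
                   permutation: np.ndarray) -> tuple[float, float]:
    """Root mean squared errors of the tables (pooled over all entries)
    and of alpha, after applying the profile permutation to the estimates."""
    perm = np.asarray(permutation, dtype=np.int64)
    K = ref_tables.K
    if sorted(perm.tolist()) != list(range(K)):
        raise ValueError(f"permutation {perm} is not a bijection on 0..{K - 1}")
    E = est_tables.stacked()[:, perm]
    R = ref_tables.stacked()
    if E.shape != R.shape:
        raise ValueError("table shapes differ")
    rmse_lambda = float(np.sqrt(np.mean((E - R) ** 2)))
    ea = np.asarray(est_alpha, dtype=float)[perm]
    ra = np.asarray(ref_alpha, dtype=float)
    rmse_alpha = float(np.sqrt(np.mean((ea - ra) ** 2)))
    return rmse_lambda, rmse_alpha


def adjusted_rand_index(s1: Sequence[int], s2: Sequence[int]) -> float:
    """Chance-corrected agreement between two partitions (1 = identical
    clusterings up to label permutation)."""
    s1 = np.asarray(s1)
    s2 = np.asarray(s2)
    if s1.shape != s2.shape:
        raise ValueError("partitions must have equal length")
    return float(adjusted_rand_score(s1, s2))


def waic(samples: PosteriorSamples) -> tuple[float, float, float]:
    """Widely applicable information criterion from stored pointwise draws.

    ``lppd = sum_i log mean_t p(y_i | theta_t)`` (log-mean-exp for
    stability) and ``p_waic2 = sum_i var_t log p(y_i | theta_t)`` with the
    ``(T-1)``-denominator variance; ``WAIC = -2 (lppd - p_waic2)``.
    Returns ``(waic, lppd, p_waic2)``.
    """
    ll = samples.loglik
    T = ll.shape[0]
    if T < 2:
        raise ValueError("need at least two retained draws for the variance")
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(T)))
    p2 = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return -2.0 * (lppd - p2), lppd, p2


def summarize_fit(samples: PosteriorSamples,
                  ref_tables: Optional[ItemProbTables] = None) -> FitSummary:
    """Posterior-mode grouping, posterior means, and WAIC for one run.

    When reference tables are supplied the profile permutation aligning the
    posterior-mean tables to them is computed and applied to the reported
    means.
    """
    grouping = grouping_posterior_mode(samples.s, samples.G)
    mean_tables = samples.mean_tables()
    mean_alpha = samples.mean_alpha()
    perm = None
    if ref_tables is not None:
        perm = align_profiles(mean_tables, ref_tables)
        mean_tables, mean_alpha = apply_permutation(mean_tables, mean_alpha, perm)
    w, lppd, p2 = waic(samples)
    occupied = np.unique(grouping.s)
    return FitSummary(
        grouping=grouping, mean_tables=mean_tables, mean_alpha=mean_alpha,
        permutation=perm, waic=w, lppd=lppd, p_waic2=p2,
        has_empty_group=occupied.size < samples.G)


@dataclass(frozen=True)
class SelectionResult:
    """Grid of WAIC values and the selected latent dimensions."""

    table: pd.DataFrame
    best_G: Optional[int]
    best_K: Optional[int]

    @property
    def selected(self) -> Optional[tuple[int, int]]:
        if self.best_G is None:
            return None
        return self.best_G, self.best_K


def select_dimensions(data: ResponseMatrix, G_grid: Sequence[int],
                      K_grid: Sequence[int], config: MCMCConfig,
                      ) -> SelectionResult:
    """Fit every (G, K) cell and pick the smallest WAIC among usable fits.

    A fit whose posterior-mode grouping leaves some group empty is excluded
    from selection (empty groups cannot be assigned meaning), even when its
    WAIC is smallest.  Returns the full grid table for inspection; when all
    candidates are excluded ``best_G``/``best_K`` are ``None``.
    """
    rows = []
    for G in G_grid:
        for K in K_grid:
            samples = run_chain(data, int(G), int(K), config)
            summary = summarize_fit(samples)
            rows.append({"G": int(G), "K": int(K), "waic": summary.waic,
                         "lppd": summary.lppd, "p_waic2": summary.p_waic2,
                         "empty_group": summary.has_empty_group})
    table = pd.DataFrame(rows)
    usable = table[~table["empty_group"]]
    if usable.empty:
        return SelectionResult(table=table, best_G=None, best_K=None)
    best = usable.loc[usable["waic"].idxmin()]
    return SelectionResult(table=table, best_G=int(best["G"]),
                           best_K=int(best["K"]))


# ---------------------------------------------------------------------------
# Cramér's V
# ---------------------------------------------------------------------------


def _v_from_joint(P: np.ndarray) -> float:
    """Population Cramér's V from a joint probability table."""
    rows = P.sum(axis=1)
    cols = P.sum(axis=0)
    expected = np.outer(rows, cols)
    mask = expected > 0
    phi2 = float(np.sum((P[mask] - expected[mask]) ** 2 / expected[mask]))
    denom = min(P.shape[0] - 1, P.shape[1] - 1)
    if denom == 0:
        return 0.0
    return float(np.sqrt(phi2 / denom))


def cramers_v_sample(data: ResponseMatrix) -> np.ndarray:
    """Pairwise sample Cramér's V matrix from observed contingency tables.

    ``V = sqrt(chi2 / (n * min(d_j - 1, d_j' - 1)))``; the diagonal is set
    to 1 and an item with a single observed category gets 0 against every
    partner.
    """
    y, d = data.y, data.domain.d
    p, n = data.p, data.n
    V = np.eye(p)
    onehot = [np.eye(d[j], dtype=np.int64)[y[:, j]] for j in range(p)]
    for j in range(p):
        for j2 in range(j + 1, p):
            counts = onehot[j].T @ onehot[j2]
            P = counts / n
            v = _v_from_joint(P)
            V[j, j2] = V[j2, j] = v
    return V


def cramers_v_model(grouping: Grouping, tables: ItemProbTables,
                    alpha: DirichletParams) -> np.ndarray:
    """Pairwise model-implied Cramér's V matrix (population version).

    Applies the mean-square-contingency formula to the model's two-item
    marginal probability tables instead of observed counts, so the result
    is free of sampling noise and depends only on the parameters.
    """
    p = tables.p
    V = np.eye(p)
    for j in range(p):
        for j2 in range(j + 1, p):
            P = pairwise_marginal(j, j2, grouping, tables, alpha)
            v = _v_from_joint(P)
            V[j, j2] = V[j2, j] = v
    return V
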