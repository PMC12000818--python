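"""Posterior samplers for the Dirichlet dimension-grouped mixed membership model.

Two samplers share all conditional updates for the tables, memberships,
assignments and grouping, and differ in how they treat the Dirichlet
concentrations ``alpha``:

* ``mh_within_gibbs`` — a Metropolis-Hastings move with independent
  lognormal proposals on each ``alpha_k``, targeting the posterior induced
  by a ``Gamma(a_alpha, b_alpha)`` hyperprior on ``alpha_0`` and a uniform
  prior on ``alpha / alpha_0``;
* ``gibbs_augmented`` — a fully conjugate update after augmenting the
  Dirichlet-multinomial assignment counts with Beta and Chinese Restaurant
  Table (CRT) auxiliary variables, under independent ``Gamma(a0, b0)``
  priors on each ``alpha_k``.

No ordering constraint is imposed on the profiles during sampling; label
switching is resolved after the fact (:func:`gromm.postprocess.align_profiles`).
Update order within a sweep is tables, memberships, assignments,
(grouping, group weights), concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import gammaln, logsumexp

from . import _kernels
from .model_core import (
    DirichletParams,
    Grouping,
    ItemProbTables,
    ResponseMatrix,
)

__all__ = [
    "MCMCConfig",
    "ChainState",
    "PosteriorSamples",
    "run_chain",
    "initial_state",
    "sweep",
    "split_merge_move",
    "update_lambda",
    "update_pi",
    "update_z",
    "update_grouping",
    "update_alpha_mh",
    "update_alpha_gibbs",
    "sample_crt",
    "z_full_conditional_probs",
    "s_full_conditional_probs",
    "pointwise_loglik",
    "resample_data",
]

_SAMPLERS = ("mh_within_gibbs", "gibbs_augmented")


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings and hyperparameters.

    ``sigma_alpha`` is the lognormal proposal scale of the MH concentration
    move; ``(a_alpha, b_alpha)`` the Gamma hyperprior (shape, rate) on
    ``alpha_0`` for the MH path; ``(a0, b0)`` the per-``alpha_k`` Gamma
    prior for the augmented Gibbs path.  Defaults follow the benchmark
    simulation protocol: 15000 sweeps, 10000 burn-in, thinning 5,
    ``(a_alpha, b_alpha) = (2, 1)``, ``sigma_alpha = 0.02``.
    """

    iterations: int = 15000
    burn_in: int = 10000
    thin: int = 5
    sampler: str = "mh_within_gibbs"
    sigma_alpha: float = 0.02
    a_alpha: float = 2.0
    b_alpha: float = 1.0
    a0: float = 1.0
    b0: float = 1.0
    seed: int = 0
    init: str = "prior_random"
    store_pi: bool = False
    store_z: bool = False
    acceptance_window: int = 100
    split_merge_attempts: int = 3
    split_merge_every: int = 5
    warmup: int = -1
    warmup_alpha: float = 0.1

    def __post_init__(self):
        if self.sampler not in _SAMPLERS:
            raise ValueError(f"sampler must be one of {_SAMPLERS}")
        if self.init not in ("prior_random", "provided"):
            raise ValueError("init must be 'prior_random' or 'provided'")
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("need 0 <= burn_in < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.sigma_alpha <= 0:
            raise ValueError("sigma_alpha must be positive")
        for name in ("a_alpha", "b_alpha", "a0", "b0", "warmup_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.split_merge_attempts < 0:
            raise ValueError("split_merge_attempts must be >= 0")
        if self.split_merge_every < 1:
            raise ValueError("split_merge_every must be >= 1")
        if self.warmup > self.burn_in:
            raise ValueError("need warmup <= burn_in")

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burn_in) // self.thin

    @property
    def effective_warmup(self) -> int:
        """Warm-up length; negative means auto (500 capped at burn_in/2)."""
        if self.warmup >= 0:
            return self.warmup
        return min(500, self.burn_in // 2)


@dataclass
class ChainState:
    """Mutable sampler state; arrays are updated in place by the kernels.

    ``lam`` is ``p x d_max x K`` (padded over categories), ``pi`` is
    ``n x K``, ``z`` is ``n x G``, ``s`` length ``p`` (0-based group
    labels), ``xi`` the group-weight simplex, ``alpha`` the concentrations.
    """

    lam: np.ndarray
    loglam: np.ndarray
    pi: np.ndarray
    z: np.ndarray
    s: np.ndarray
    xi: np.ndarray
    alpha: np.ndarray
    d: np.ndarray
    G: int
    iteration: int = 0
    accept_count: int = 0
    mh_proposals: int = 0

    @property
    def n(self) -> int:
        return self.pi.shape[0]

    @property
    def p(self) -> int:
        return self.lam.shape[0]

    @property
    def K(self) -> int:
        return self.alpha.shape[0]

    def tables(self) -> ItemProbTables:
        return ItemProbTables([self.lam[j, :self.d[j], :] for j in range(self.p)])

    def grouping(self) -> Grouping:
        return Grouping(self.s, self.G)


@dataclass(frozen=True)
class PosteriorSamples:
    """Thinned posterior draws with per-draw pointwise log-likelihoods.

    ``lam`` is ``T x p x d_max x K``; ``s`` is ``T x p``; ``alpha`` is
    ``T x K``; ``xi`` is ``T x G``; ``loglik`` is ``T x n`` holding
    ``log p(y_i | theta^(t))`` evaluated at storage time.  ``pi`` / ``z``
    draws are retained only when requested in the config.
    """

    lam: np.ndarray
    s: np.ndarray
    alpha: np.ndarray
    xi: np.ndarray
    loglik: np.ndarray
    d: np.ndarray
    G: int
    K: int
    config: MCMCConfig
    acceptance_rate: Optional[float] = None
    acceptance_trace: Optional[np.ndarray] = None
    pi: Optional[np.ndarray] = None
    z: Optional[np.ndarray] = None

    @property
    def n_draws(self) -> int:
        return self.lam.shape[0]

    @property
    def p(self) -> int:
        return self.lam.shape[1]

    def tables_at(self, t: int) -> ItemProbTables:
        return ItemProbTables(
            [self.lam[t, j, :self.d[j], :] for j in range(self.p)])

    def mean_tables(self) -> ItemProbTables:
        """Posterior-mean conditional probability tables (no relabeling)."""
        m = self.lam.mean(axis=0)
        return ItemProbTables([m[j, :self.d[j], :] for j in range(self.p)])

    def mean_alpha(self) -> np.ndarray:
        return self.alpha.mean(axis=0)


# ---------------------------------------------------------------------------
# state construction
# ---------------------------------------------------------------------------


def initial_state(data: ResponseMatrix, G: int, K: int, config: MCMCConfig,
                  rng: np.random.Generator,
                  provided: Optional[ChainState] = None) -> ChainState:
    """Build the starting state, by default drawing every unknown from its prior."""
    if provided is not None:
        return provided
    n, p = data.n, data.p
    d = np.asarray(data.domain.d, dtype=np.int64)
    dmax = int(d.max())
    xi = rng.dirichlet(np.ones(G))
    s = rng.choice(G, size=p, p=xi).astype(np.int64)
    lam = np.zeros((p, dmax, K))
    for j in range(p):
        lam[j, :d[j], :] = rng.dirichlet(np.ones(d[j]), size=K).T
    if config.sampler == "mh_within_gibbs":
        alpha0 = rng.gamma(config.a_alpha, 1.0 / config.b_alpha)
        eta = rng.dirichlet(np.ones(K))
        alpha = alpha0 * eta
    else:
        alpha = rng.gamma(config.a0, 1.0 / config.b0, size=K)
    alpha = np.maximum(alpha, 1e-8)
    pi = rng.dirichlet(alpha, size=n) if K > 1 else np.ones((n, 1))
    pi = np.maximum(pi, 1e-300)
    pi /= pi.sum(axis=1, keepdims=True)
    z = np.empty((n, G), dtype=np.int64)
    cdf = np.cumsum(pi, axis=1)
    for g in range(G):
        z[:, g] = (rng.random((n, 1)) > cdf).sum(axis=1)
    with np.errstate(divide="ignore"):
        loglam = np.where(lam > 0, np.log(np.maximum(lam, 1e-300)), -np.inf)
    loglam[lam == 0] = -746.0  # effectively -inf but finite for the kernels
    return ChainState(lam=lam, loglam=loglam, pi=pi, z=z, s=s, xi=xi,
                      alpha=alpha.astype(float), d=d, G=int(G))


# ---------------------------------------------------------------------------
# conditional updates (thin wrappers over the compiled kernels)
# ---------------------------------------------------------------------------


def update_lambda(state: ChainState, data: ResponseMatrix) -> ChainState:
    """Redraw all table columns from their conjugate Dirichlet conditionals."""
    _kernels.update_lambda_kernel(data.y, state.d, state.z, state.s,
                                  state.lam, state.loglam)
    return state


def update_pi(state: ChainState, data: ResponseMatrix) -> ChainState:
    """Redraw memberships: ``pi_i ~ Dirichlet(alpha + assignment counts)``."""
    _kernels.update_pi_kernel(state.z, state.alpha, state.pi)
    return state


def update_z(state: ChainState, data: ResponseMatrix) -> ChainState:
    """Redraw assignments from their categorical full conditionals."""
    _kernels.update_z_kernel(data.y, state.z, state.s, state.loglam, state.pi)
    return state


def update_grouping(state: ChainState, data: ResponseMatrix,
                    beta: float = 1.0) -> ChainState:
    """Redraw the item grouping ``s``, then the group weights ``xi``.

    ``beta`` tempers the likelihood term (exact conditional at 1.0); used
    below 1 only during the burn-in warm-up.
    """
    _kernels.update_s_kernel(data.y, state.z, state.s, state.xi,
                             state.loglam, beta)
    return state


def update_alpha_mh(state: ChainState, config: MCMCConfig) -> ChainState:
    """One MH move on alpha; acceptance recorded on the state."""
    acc = _kernels.update_alpha_mh_kernel(
        state.pi, state.alpha, config.a_alpha, config.b_alpha,
        config.sigma_alpha)
    state.accept_count += int(acc)
    state.mh_proposals += 1
    return state


def update_alpha_gibbs(state: ChainState, config: MCMCConfig) -> ChainState:
    """Conjugate augmented (Beta / CRT / Gamma) update of alpha."""
    _kernels.update_alpha_gibbs_kernel(state.z, state.alpha,
                                       config.a0, config.b0)
    return state


def sample_crt(m: int, r: float, rng: Optional[np.random.Generator] = None,
               seed: Optional[int] = None) -> int:
    """Draw a Chinese Restaurant Table count: tables opened by ``m``
    customers under concentration ``r``.

    ``t = sum_{l=1}^{m} Bernoulli(r / (r + l - 1))``, so ``t`` lies in
    ``[min(1, m), m]``.  When ``rng``/``seed`` is given, the kernel RNG is
    reseeded first (the kernels share numba's global RNG stream).
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    if r <= 0:
        raise ValueError("concentration r must be positive")
    if seed is not None:
        _kernels.seed_rng(seed)
    elif rng is not None:
        _kernels.seed_rng(int(rng.integers(2**31 - 1)))
    return int(_kernels.crt_draw(int(m), float(r)))


# ---------------------------------------------------------------------------
# full-conditional probabilities in plain numpy (reference formulas)
# ---------------------------------------------------------------------------


def z_full_conditional_probs(state: ChainState, data: ResponseMatrix,
                             i: int, g: int) -> np.ndarray:
    """P(z_{i,g} = k | -) over k, by direct evaluation of the formula."""
    logp = np.log(state.pi[i]).astype(float)
    for j in np.flatnonzero(state.s == g):
        logp = logp + state.loglam[j, data.y[i, j], :]
    logp -= logsumexp(logp)
    return np.exp(logp)


def s_full_conditional_probs(state: ChainState, data: ResponseMatrix,
                             j: int) -> np.ndarray:
    """P(s_j = g | -) over g, by direct evaluation of the formula."""
    logp = np.log(state.xi).astype(float)
    for g in range(state.G):
        logp[g] += state.loglam[j, data.y[:, j], state.z[:, g]].sum()
    logp -= logsumexp(logp)
    return np.exp(logp)


def pointwise_loglik(state: ChainState, data: ResponseMatrix) -> np.ndarray:
    """Vector of ``log p(y_i | theta)`` at the current state."""
    out = np.empty(data.n)
    _kernels.pointwise_loglik_kernel(data.y, state.s, state.G, state.loglam,
                                     state.pi, out)
    return out


def resample_data(state: ChainState, data: ResponseMatrix) -> None:
    """Redraw the response matrix in place given the current state.

    Used by the joint-consistency (successive-conditional) simulator; the
    array inside ``data`` is temporarily made writable.
    """
    data.y.flags.writeable = True
    try:
        _kernels.resample_y_kernel(data.y, state.d, state.z, state.s, state.lam)
    finally:
        data.y.flags.writeable = False


# ---------------------------------------------------------------------------
# split-merge moves on the grouping
# ---------------------------------------------------------------------------
#
# The single-site grouping update relocates one item at a time against
# frozen assignment columns, frozen tables and frozen memberships, so the
# chain gets trapped in modes where two item groups share one assignment
# column: no single-item move can pay the cost of opening a fresh column.
# The split-merge pair below relocates a whole item subset together with a
# freshly proposed column.  Tables of the affected items and the
# membership matrix are redrawn from their conjugate conditionals as part
# of the move, which telescopes their densities into Dirichlet-multinomial
# marginal-likelihood ratios and Polya-urn assignment priors — the
# acceptance ratio therefore compares table-free evidence for the two
# groupings.  Proposals follow the anchored launch-and-allocate recipe of
# Jain & Neal's split-merge sampler: a random bipartition is refined by
# restricted scans in which both candidate columns are re-estimated, and
# only the final scan's probabilities enter the proposal density.  The
# launch uses posterior-mean table estimates computed from counts, never
# the current table draws, so its distribution is identical from both ends
# of the move.  The moves are ordinary Metropolis-Hastings on the exact
# posterior.

_LAUNCH_SCANS = 2


def _other_col_counts(state: ChainState, g: int, g2: Optional[int] = None
                      ) -> np.ndarray:
    """c[i, k] = number of columns outside {g, g2} with z_{i, .} = k."""
    n, K = state.n, state.K
    cnt = np.zeros((n, K))
    rows = np.arange(n)
    for gg in range(state.G):
        if gg != g and gg != g2:
            cnt[rows, state.z[:, gg]] += 1.0
    return cnt


def _draw_column(w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    wn = w / w.sum(axis=1, keepdims=True)
    return (rng.random((w.shape[0], 1)) > np.cumsum(wn, axis=1)).sum(axis=1)


def _col_logdens(w: np.ndarray, col: np.ndarray) -> float:
    """log probability of ``col`` under the normalized weights ``w``."""
    wn = w / w.sum(axis=1, keepdims=True)
    return float(np.log(wn[np.arange(w.shape[0]), col]).sum())


def _item_counts(state: ChainState, y: np.ndarray, l: int,
                 col: np.ndarray) -> np.ndarray:
    dj = int(state.d[l])
    flat = np.bincount(col * dj + y[:, l], minlength=state.K * dj)
    return flat.reshape(state.K, dj).astype(float)


def _item_col_logml(state: ChainState, y: np.ndarray, l: int,
                    col: np.ndarray) -> float:
    """Dirichlet-multinomial log marginal of item l's data given a column,
    up to an additive constant shared by all columns."""
    return float(_kernels.col_logml_kernel(y[:, l], col, int(state.d[l]),
                                           state.K))


def _table_estimate(state: ChainState, y: np.ndarray, l: int,
                    col: np.ndarray) -> np.ndarray:
    """Posterior-mean table of item l given a column: (1+n_kc)/(d_j+m_k)."""
    return _kernels.table_estimate_kernel(y[:, l], col, int(state.d[l]),
                                          state.K)


def _hat_col_weights(state, y, urnbase, items, cols) -> np.ndarray:
    """urnbase[i,k] * prod over items of their estimated P(y_il | k)."""
    w = urnbase.copy()
    for l, col in zip(items, cols):
        lhat = _table_estimate(state, y, l, col)   # K x d_l
        w *= lhat[:, y[:, l]].T
    return w


class _MlCache:
    """Memo for per-item marginal scores against a fixed stay column."""

    def __init__(self, state, y, col):
        self.state, self.y, self.col = state, y, col
        self._vals: dict[int, float] = {}

    def __call__(self, l: int) -> float:
        if l not in self._vals:
            self._vals[l] = _item_col_logml(self.state, self.y, l, self.col)
        return self._vals[l]


def _alloc_prob(state, y, l, colD, stay_ml, lxiD, lxiR) -> float:
    """Probability the allocation scan sends item l to the fresh (D) side.

    ``stay_ml`` is an :class:`_MlCache` over the stay-side column, which is
    fixed for the whole attempt.
    """
    diff = (stay_ml(l) + lxiR) \
        - (_item_col_logml(state, y, l, colD) + lxiD)
    if diff > 700.0:
        diff = 700.0
    q = 1.0 / (1.0 + np.exp(diff))
    return min(max(q, 1e-300), 1.0 - 1e-16)


def _launch(state, y, rng, j1, j2, members, urnbase, lxiD, lxiR):
    """Shared launch: random bipartition refined by restricted scans.

    Returns the launch columns (colD, colR); depends only on the anchors,
    the member set, the data and the urn base, never on the current tables
    or columns, so both move directions replay the same distribution.
    """
    D, R = [j1], [j2]
    for l in members:
        (D if rng.random() < 0.5 else R).append(l)
    un = urnbase / urnbase.sum(axis=1, keepdims=True)
    colD = _draw_column(un, rng)
    colR = _draw_column(un, rng)
    for _ in range(_LAUNCH_SCANS):
        newD, newR = [j1], [j2]
        ml_R = _MlCache(state, y, colR)
        for l in members:
            if rng.random() < _alloc_prob(state, y, l, colD, ml_R, lxiD, lxiR):
                newD.append(l)
            else:
                newR.append(l)
        wD = _hat_col_weights(state, y, urnbase, newD, [colD] * len(newD))
        wR = _hat_col_weights(state, y, urnbase, newR, [colR] * len(newR))
        colD = _draw_column(wD, rng)
        colR = _draw_column(wR, rng)
        D, R = newD, newR
    return colD, colR


def split_merge_move(state: ChainState, data: ResponseMatrix,
                     rng: np.random.Generator, attempts: int = 1) -> int:
    """Anchored split-merge Metropolis-Hastings moves on the grouping.

    Each attempt draws two anchor items.  Anchors sharing a group propose
    splitting that group into itself and a currently empty group; anchors
    in different groups propose merging the first anchor's group into the
    second's.  Returns the number of accepted moves.
    """
    y = data.y
    G = state.G
    if state.p < 2 or G < 2 or state.K < 2:
        return 0
    accepted = 0
    for _ in range(attempts):
        j1 = int(rng.integers(state.p))
        j2 = int(rng.integers(state.p - 1))
        if j2 >= j1:
            j2 += 1
        g1, g2 = int(state.s[j1]), int(state.s[j2])
        occ = np.bincount(state.s, minlength=G)
        empties = np.flatnonzero(occ == 0)
        keep = rng.random() < 0.5
        if g1 == g2:
            if empties.size == 0:
                continue
            gp = int(empties[rng.integers(empties.size)])
            if keep:
                accepted += _try_split_keep(state, y, rng, j1, j2, g1, gp,
                                            empties.size)
            else:
                accepted += _try_split(state, y, rng, j1, j2, g1, gp,
                                       empties.size)
        else:
            if keep:
                accepted += _try_merge_keep(state, y, rng, j1, j2, g1, g2,
                                            empties.size)
            else:
                accepted += _try_merge(state, y, rng, j1, j2, g1, g2,
                                       empties.size)
    return accepted


def _launch_keep(state, y, rng, j1, j2, members, urnbase, ml_b0, lxiD, lxiR):
    """Launch for the column-keeping variant: only the fresh column evolves.

    The stay-side column ``b0`` is identical in both endpoint states of the
    move, so using it in the launch keeps the construction symmetric.
    """
    colD = _draw_column(
        _hat_col_weights(state, y, urnbase, [j1], [ml_b0.col]), rng)
    D = [j1]
    for _ in range(_LAUNCH_SCANS):
        newD = [j1]
        for l in members:
            if rng.random() < _alloc_prob(state, y, l, colD, ml_b0,
                                          lxiD, lxiR):
                newD.append(l)
        colD = _draw_column(
            _hat_col_weights(state, y, urnbase, newD, [colD] * len(newD)),
            rng)
        D = newD
    return colD


def _try_split_keep(state, y, rng, j1, j2, g0, gp, n_empty) -> int:
    """Split where the remaining group keeps its current column.

    Cheap nucleation: only the departing subset pays for a fresh column, so
    small well-supported subgroups can leave a large consensus group.
    """
    lxi = np.log(state.xi)
    members = [int(l) for l in np.flatnonzero(state.s == g0)
               if l not in (j1, j2)]
    b0 = state.z[:, g0]
    urnbase = state.alpha[None, :] + _other_col_counts(state, gp)
    alpha0G = float(state.alpha.sum()) + state.G - 1.0
    ml_b0 = _MlCache(state, y, b0)
    colD = _launch_keep(state, y, rng, j1, j2, members, urnbase, ml_b0,
                        lxi[gp], lxi[g0])
    D = [j1]
    log_alloc = 0.0
    for l in members:
        q = _alloc_prob(state, y, l, colD, ml_b0, lxi[gp], lxi[g0])
        if rng.random() < q:
            D.append(l)
            log_alloc += np.log(q)
        else:
            log_alloc += np.log1p(-q)
    wD = _hat_col_weights(state, y, urnbase, D, [colD] * len(D))
    cD = _draw_column(wD, rng)
    rows = np.arange(state.n)
    delta_ml = sum(_item_col_logml(state, y, l, cD) - ml_b0(l) for l in D)
    log_r = (len(D) * (lxi[gp] - lxi[g0]) + delta_ml
             + np.log(urnbase[rows, cD]).sum() - state.n * np.log(alpha0G)
             - _col_logdens(wD, cD)
             + np.log(float(n_empty)) - log_alloc)
    if not np.isfinite(log_r) or np.log(rng.random()) >= log_r:
        return 0
    state.z[:, gp] = cD
    for l in D:
        state.s[l] = gp
        _conjugate_table_redraw(state, y, l, cD, rng)
    _kernels.update_pi_kernel(state.z, state.alpha, state.pi)
    return 1


def _try_merge_keep(state, y, rng, j1, j2, gA, gB, n_empty) -> int:
    """Absorb group gA into gB, keeping gB's column."""
    lxi = np.log(state.xi)
    D = [int(l) for l in np.flatnonzero(state.s == gA)]
    R = [int(l) for l in np.flatnonzero(state.s == gB)]
    members = [l for l in D + R if l not in (j1, j2)]
    cD = state.z[:, gA].copy()
    b0 = state.z[:, gB]
    urnbase = state.alpha[None, :] + _other_col_counts(state, gA)
    alpha0G = float(state.alpha.sum()) + state.G - 1.0
    ml_b0 = _MlCache(state, y, b0)
    colD = _launch_keep(state, y, rng, j1, j2, members, urnbase, ml_b0,
                        lxi[gA], lxi[gB])
    log_alloc = 0.0
    for l in members:
        q = _alloc_prob(state, y, l, colD, ml_b0, lxi[gA], lxi[gB])
        log_alloc += np.log(q) if state.s[l] == gA else np.log1p(-q)
    wD = _hat_col_weights(state, y, urnbase, D, [colD] * len(D))
    rows = np.arange(state.n)
    delta_ml = sum(ml_b0(l) - _item_col_logml(state, y, l, cD) for l in D)
    log_r = (len(D) * (lxi[gB] - lxi[gA]) + delta_ml
             - np.log(urnbase[rows, cD]).sum() + state.n * np.log(alpha0G)
             + _col_logdens(wD, cD)
             + log_alloc - np.log(float(n_empty + 1)))
    if not np.isfinite(log_r) or np.log(rng.random()) >= log_r:
        return 0
    for l in D:
        state.s[l] = gB
        _conjugate_table_redraw(state, y, l, b0, rng)
    un = urnbase / urnbase.sum(axis=1, keepdims=True)
    state.z[:, gA] = _draw_column(un, rng)
    _kernels.update_pi_kernel(state.z, state.alpha, state.pi)
    return 1


def _try_split(state, y, rng, j1, j2, g0, gp, n_empty) -> int:
    lxi = np.log(state.xi)
    members = [int(l) for l in np.flatnonzero(state.s == g0)
               if l not in (j1, j2)]
    b0 = state.z[:, g0].copy()
    urnbase = state.alpha[None, :] + _other_col_counts(state, g0, gp)
    alpha0G = float(state.alpha.sum()) + state.G
    colD, colR = _launch(state, y, rng, j1, j2, members, urnbase,
                         lxi[gp], lxi[g0])
    # final allocation; probabilities enter the proposal density
    D, R = [j1], [j2]
    ml_colR = _MlCache(state, y, colR)
    log_alloc = 0.0
    for l in members:
        q = _alloc_prob(state, y, l, colD, ml_colR, lxi[gp], lxi[g0])
        if rng.random() < q:
            D.append(l)
            log_alloc += np.log(q)
        else:
            R.append(l)
            log_alloc += np.log1p(-q)
    # final columns: R first from the urn, then D given R's draw
    wR = _hat_col_weights(state, y, urnbase, R, [colR] * len(R))
    cR = _draw_column(wR, rng)
    onehot = np.zeros_like(urnbase)
    onehot[np.arange(state.n), cR] = 1.0
    wD = _hat_col_weights(state, y, urnbase + onehot, D, [colD] * len(D))
    cD = _draw_column(wD, rng)
    # reverse merge would propose the old shared column from hat-estimates
    # taken against the proposed split columns
    wB = _hat_col_weights(state, y, urnbase,
                          D + R, [cD] * len(D) + [cR] * len(R))
    delta_ml = sum(_item_col_logml(state, y, l, cD)
                   - _item_col_logml(state, y, l, b0) for l in D)
    delta_ml += sum(_item_col_logml(state, y, l, cR)
                    - _item_col_logml(state, y, l, b0) for l in R)
    rows = np.arange(state.n)
    log_urn_new = (np.log(urnbase[rows, cR]).sum()
                   + np.log((urnbase + onehot)[rows, cD]).sum()
                   - state.n * (np.log(alpha0G - 2.0) + np.log(alpha0G - 1.0)))
    log_urn_old = (np.log(urnbase[rows, b0]).sum()
                   - state.n * np.log(alpha0G - 2.0))
    log_r = (len(D) * (lxi[gp] - lxi[g0]) + delta_ml
             + log_urn_new - _col_logdens(wR, cR) - _col_logdens(wD, cD)
             + _col_logdens(wB, b0) - log_urn_old
             + np.log(float(n_empty)) - log_alloc)
    if not np.isfinite(log_r) or np.log(rng.random()) >= log_r:
        return 0
    state.z[:, g0] = cR
    state.z[:, gp] = cD
    for l in D:
        state.s[l] = gp
        _conjugate_table_redraw(state, y, l, cD, rng)
    for l in R:
        _conjugate_table_redraw(state, y, l, cR, rng)
    _kernels.update_pi_kernel(state.z, state.alpha, state.pi)
    return 1


def _try_merge(state, y, rng, j1, j2, gA, gB, n_empty) -> int:
    lxi = np.log(state.xi)
    D = [int(l) for l in np.flatnonzero(state.s == gA)]
    R = [int(l) for l in np.flatnonzero(state.s == gB)]
    members = [l for l in D + R if l not in (j1, j2)]
    cD = state.z[:, gA].copy()
    cR = state.z[:, gB].copy()
    urnbase = state.alpha[None, :] + _other_col_counts(state, gA, gB)
    alpha0G = float(state.alpha.sum()) + state.G
    colD, colR = _launch(state, y, rng, j1, j2, members, urnbase,
                         lxi[gA], lxi[gB])
    # dummy final scan: probability of regenerating the actual split
    log_alloc = 0.0
    ml_colR = _MlCache(state, y, colR)
    for l in members:
        q = _alloc_prob(state, y, l, colD, ml_colR, lxi[gA], lxi[gB])
        log_alloc += np.log(q) if state.s[l] == gA else np.log1p(-q)
    # forward: propose the merged column from hat-estimates against the
    # items' current columns
    wB = _hat_col_weights(state, y, urnbase,
                          D + R, [cD] * len(D) + [cR] * len(R))
    b0 = _draw_column(wB, rng)
    # reverse split column densities
    wR = _hat_col_weights(state, y, urnbase, R, [colR] * len(R))
    onehot = np.zeros_like(urnbase)
    onehot[np.arange(state.n), cR] = 1.0
    wD = _hat_col_weights(state, y, urnbase + onehot, D, [colD] * len(D))
    delta_ml = sum(_item_col_logml(state, y, l, b0)
                   - _item_col_logml(state, y, l, cD) for l in D)
    delta_ml += sum(_item_col_logml(state, y, l, b0)
                    - _item_col_logml(state, y, l, cR) for l in R)
    rows = np.arange(state.n)
    log_urn_split = (np.log(urnbase[rows, cR]).sum()
                     + np.log((urnbase + onehot)[rows, cD]).sum()
                     - state.n * (np.log(alpha0G - 2.0)
                                  + np.log(alpha0G - 1.0)))
    log_urn_merged = (np.log(urnbase[rows, b0]).sum()
                      - state.n * np.log(alpha0G - 2.0))
    log_r = (len(D) * (lxi[gB] - lxi[gA]) + delta_ml
             + log_urn_merged - _col_logdens(wB, b0)
             + _col_logdens(wR, cR) + _col_logdens(wD, cD) - log_urn_split
             + log_alloc - np.log(float(n_empty + 1)))
    if not np.isfinite(log_r) or np.log(rng.random()) >= log_r:
        return 0
    state.z[:, gB] = b0
    for l in D:
        state.s[l] = gB
    for l in D + R:
        _conjugate_table_redraw(state, y, l, b0, rng)
    # vacated column drawn from its urn conditional given the merged column
    onehot_b = np.zeros_like(urnbase)
    onehot_b[rows, b0] = 1.0
    state.z[:, gA] = _draw_column(urnbase + onehot_b, rng)
    _kernels.update_pi_kernel(state.z, state.alpha, state.pi)
    return 1


def _conjugate_table_redraw(state, y, l, col, rng) -> None:
    """Redraw item l's table from Dirichlet(1 + counts under the column)."""
    dj = int(state.d[l])
    counts = _item_counts(state, y, l, col)
    for k in range(state.K):
        state.lam[l, :dj, k] = rng.dirichlet(1.0 + counts[k])
    state.loglam[l, :dj, :] = np.log(np.maximum(state.lam[l, :dj, :], 1e-300))


# ---------------------------------------------------------------------------
# the full chain
# ---------------------------------------------------------------------------


def sweep(state: ChainState, data: ResponseMatrix, config: MCMCConfig,
          rng: Optional[np.random.Generator] = None,
          beta: float = 1.0, do_split_merge: bool = True) -> ChainState:
    """One full update cycle: Λ, Π, Z, (s, ξ), split-merge, α.

    ``beta < 1`` marks the warm-up phase of burn-in: the grouping update
    is tempered, the group weights are pinned uniform and the
    concentrations are held fixed, which keeps early group occupancy
    spread out while the grouping self-organizes.  The exact kernel
    (``beta = 1``) runs for the rest of the chain.
    """
    update_lambda(state, data)
    update_pi(state, data)
    update_z(state, data)
    update_grouping(state, data, beta=beta)
    if beta < 1.0:
        state.xi[:] = 1.0 / state.G
    elif config.sampler == "mh_within_gibbs":
        update_alpha_mh(state, config)
    else:
        update_alpha_gibbs(state, config)
    if rng is not None and config.split_merge_attempts > 0 and do_split_merge:
        split_merge_move(state, data, rng, config.split_merge_attempts)
    state.iteration += 1
    return state


def run_chain(data: ResponseMatrix, G: int, K: int, config: MCMCConfig,
              initial: Optional[ChainState] = None) -> PosteriorSamples:
    """Run one MCMC chain and return thinned posterior draws.

    Initialization draws every unknown from its prior (``init =
    'prior_random'``) unless a state is provided.  Per-draw pointwise
    log-likelihoods are evaluated at thinning time so information criteria
    are exact with respect to the retained draws.  The MH acceptance
    indicator is averaged over consecutive windows for monitoring.
    """
    if G < 1 or K < 1:
        raise ValueError("G and K must be >= 1")
    if config.init == "provided" and initial is None:
        raise ValueError("init='provided' requires an initial state")
    rng = np.random.default_rng(config.seed)
    state = initial_state(data, G, K, config, rng, provided=initial)
    if state.G != G or state.K != K:
        raise ValueError("provided state inconsistent with (G, K)")
    _kernels.seed_rng(int(rng.integers(2**31 - 1)))
    warmup = config.effective_warmup if G > 1 else 0
    if warmup > 0:
        state.alpha[:] = config.warmup_alpha
        state.xi[:] = 1.0 / G

    T = config.n_draws
    n, p, dmax = data.n, data.p, state.lam.shape[1]
    lam_draws = np.empty((T, p, dmax, K))
    s_draws = np.empty((T, p), dtype=np.int64)
    alpha_draws = np.empty((T, K))
    xi_draws = np.empty((T, G))
    loglik_draws = np.empty((T, n))
    pi_draws = np.empty((T, n, K)) if config.store_pi else None
    z_draws = np.empty((T, n, G), dtype=np.int64) if config.store_z else None

    accept_trace = []
    window_acc = 0
    window_prop = 0
    t = 0
    for it in range(config.iterations):
        before = state.accept_count
        props_before = state.mh_proposals
        beta = min(1.0, it / warmup) if warmup > 0 else 1.0
        # split-merge runs every sweep while the grouping is organizing,
        # then on a fixed schedule (kernel composition stays exact)
        do_sm = beta < 1.0 or it % config.split_merge_every == 0
        sweep(state, data, config, rng=rng, beta=beta, do_split_merge=do_sm)
        window_acc += state.accept_count - before
        window_prop += state.mh_proposals - props_before
        if window_prop >= config.acceptance_window:
            accept_trace.append(window_acc / window_prop)
            window_acc = 0
            window_prop = 0
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 \
                and t < T:
            lam_draws[t] = state.lam
            s_draws[t] = state.s
            alpha_draws[t] = state.alpha
            xi_draws[t] = state.xi
            _kernels.pointwise_loglik_kernel(
                data.y, state.s, state.G, state.loglam, state.pi,
                loglik_draws[t])
            if pi_draws is not None:
                pi_draws[t] = state.pi
            if z_draws is not None:
                z_draws[t] = state.z
            t += 1
    if window_prop > 0:
        accept_trace.append(window_acc / window_prop)
    acc_rate = (state.accept_count / state.mh_proposals
                if state.mh_proposals else None)
    return PosteriorSamples(
        lam=lam_draws, s=s_draws, alpha=alpha_draws, xi=xi_draws,
        loglik=loglik_draws, d=state.d, G=G, K=K, config=config,
        acceptance_rate=acc_rate,
        acceptance_trace=np.array(accept_trace) if accept_trace else None,
        pi=pi_draws, z=z_draws)
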