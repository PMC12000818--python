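"""Numba-compiled inner loops of the Gibbs / MH-within-Gibbs samplers.

Every kernel mutates preallocated state arrays in place and draws from
numba's global per-thread RNG, seeded once per chain via :func:`seed_rng`.
Item tables are padded to ``d_max`` categories; entries beyond an item's
``d_j`` are never touched because responses are validated to lie in range.

The pure-Python full-conditional formulas live in :mod:`gromm.mcmc`; these
kernels are their vectorized counterparts and are cross-checked against
them in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_NJIT_KW = dict(cache=True, fastmath=False)


@njit(**_NJIT_KW)
def seed_rng(seed):
    np.random.seed(seed)


@njit(**_NJIT_KW)
def _dirichlet_inplace(shape_params, out):
    """Draw Dirichlet(shape_params) into out via normalized gammas.

    Gamma draws with very small shapes can underflow to exactly zero;
    components are floored at the smallest positive normal double so that
    downstream log-probabilities stay finite.
    """
    tot = 0.0
    for i in range(shape_params.shape[0]):
        v = np.random.gamma(shape_params[i], 1.0)
        if v < 2.2250738585072014e-308:
            v = 2.2250738585072014e-308
        out[i] = v
        tot += v
    for i in range(shape_params.shape[0]):
        out[i] /= tot


@njit(**_NJIT_KW)
def _categorical_from_weights(w, K):
    """Sample an index proportional to the first K entries of w."""
    tot = 0.0
    for k in range(K):
        tot += w[k]
    u = np.random.random() * tot
    acc = 0.0
    for k in range(K - 1):
        acc += w[k]
        if u <= acc:
            return k
    return K - 1


@njit(**_NJIT_KW)
def update_lambda_kernel(y, d, z, s, lam, loglam):
    """Conjugate Dirichlet redraw of every table column.

    Column (j, k) gets Dirichlet(1 + category counts among subjects whose
    group-s_j assignment equals k); unused profiles revert to the uniform
    Dirichlet prior.
    """
    n, p = y.shape
    K = lam.shape[2]
    dmax = lam.shape[1]
    cnt = np.zeros((dmax, K))
    for j in range(p):
        g = s[j]
        dj = d[j]
        for c in range(dj):
            for k in range(K):
                cnt[c, k] = 0.0
        for i in range(n):
            cnt[y[i, j], z[i, g]] += 1.0
        for k in range(K):
            tot = 0.0
            for c in range(dj):
                v = np.random.gamma(1.0 + cnt[c, k], 1.0)
                lam[j, c, k] = v
                tot += v
            for c in range(dj):
                lam[j, c, k] /= tot
                loglam[j, c, k] = math.log(lam[j, c, k])


@njit(**_NJIT_KW)
def update_pi_kernel(z, alpha, pi):
    """Redraw each membership row from Dirichlet(alpha + assignment counts)."""
    n, G = z.shape
    K = alpha.shape[0]
    shape = np.empty(K)
    for i in range(n):
        for k in range(K):
            shape[k] = alpha[k]
        for g in range(G):
            shape[z[i, g]] += 1.0
        _dirichlet_inplace(shape, pi[i])


@njit(**_NJIT_KW)
def update_z_kernel(y, z, s, loglam, pi):
    """Redraw each assignment from its categorical full conditional.

    P(z_{i,g} = k) ∝ pi_{i,k} * prod_{j: s_j = g} lambda_{j, y_ij, k},
    accumulated in log space and sampled after a per-(i, g) max shift.
    """
    n, p = y.shape
    G = z.shape[1]
    K = pi.shape[1]
    A = np.empty((n, G, K))
    for i in range(n):
        for g in range(G):
            for k in range(K):
                A[i, g, k] = math.log(pi[i, k])
    for j in range(p):
        g = s[j]
        for i in range(n):
            c = y[i, j]
            for k in range(K):
                A[i, g, k] += loglam[j, c, k]
    w = np.empty(K)
    for i in range(n):
        for g in range(G):
            mx = A[i, g, 0]
            for k in range(1, K):
                if A[i, g, k] > mx:
                    mx = A[i, g, k]
            for k in range(K):
                w[k] = math.exp(A[i, g, k] - mx)
            z[i, g] = _categorical_from_weights(w, K)


@njit(**_NJIT_KW)
def update_s_kernel(y, z, s, xi, loglam, beta=1.0):
    """Redraw the item grouping, then the group weights.

    P(s_j = g) ∝ xi_g * [prod_i lambda_{j, y_ij, z_{i,g}}]^beta in log
    space; afterwards xi ~ Dirichlet(1 + group occupancy counts).  The
    inverse temperature ``beta`` is 1 for the exact conditional; values
    below 1 are used only during burn-in warm-up to keep early group
    occupancy spread out (annealed initialization).
    """
    n, p = y.shape
    G = xi.shape[0]
    B = np.zeros((p, G))
    for j in range(p):
        for i in range(n):
            c = y[i, j]
            for g in range(G):
                B[j, g] += loglam[j, c, z[i, g]]
    wg = np.empty(G)
    for j in range(p):
        mx = -1.0e300
        for g in range(G):
            B[j, g] = beta * B[j, g] + math.log(xi[g])
            if B[j, g] > mx:
                mx = B[j, g]
        for g in range(G):
            wg[g] = math.exp(B[j, g] - mx)
        s[j] = _categorical_from_weights(wg, G)
    shape = np.empty(G)
    for g in range(G):
        shape[g] = 1.0
    for j in range(p):
        shape[s[j]] += 1.0
    _dirichlet_inplace(shape, xi)


@njit(**_NJIT_KW)
def update_alpha_mh_kernel(pi, alpha, a_alpha, b_alpha, sigma_alpha):
    """One lognormal-proposal Metropolis-Hastings move on alpha.

    The target combines a Gamma(a_alpha, b_alpha) hyperprior on alpha_0
    with a uniform prior on alpha/alpha_0 and the Dirichlet likelihood of
    the current memberships; the acceptance ratio is evaluated in log space
    and includes the lognormal-proposal Jacobian prod_k alpha*_k/alpha_k.
    Returns 1 on acceptance, 0 otherwise.
    """
    n, K = pi.shape
    slogpi = np.zeros(K)
    for i in range(n):
        for k in range(K):
            slogpi[k] += math.log(pi[i, k])
    astar = np.empty(K)
    for k in range(K):
        astar[k] = math.exp(math.log(alpha[k]) + sigma_alpha * np.random.normal())
    a0 = 0.0
    a0s = 0.0
    for k in range(K):
        a0 += alpha[k]
        a0s += astar[k]
    logr = (a_alpha - 1.0) * (math.log(a0s) - math.log(a0)) \
        - b_alpha * (a0s - a0) \
        + n * (math.lgamma(a0s) - math.lgamma(a0))
    for k in range(K):
        logr += n * (math.lgamma(alpha[k]) - math.lgamma(astar[k]))
        logr += (astar[k] - alpha[k]) * slogpi[k]
        logr += math.log(astar[k]) - math.log(alpha[k])
    if math.log(np.random.random()) < logr:
        for k in range(K):
            alpha[k] = astar[k]
        return 1
    return 0


@njit(**_NJIT_KW)
def crt_draw(m, r):
    """Chinese Restaurant Table count: sum of Bernoulli(r / (r + l - 1))."""
    t = 0
    for l in range(1, m + 1):
        if np.random.random() < r / (r + l - 1.0):
            t += 1
    return t


@njit(**_NJIT_KW)
def update_alpha_gibbs_kernel(z, alpha, a0_prior, b0_prior):
    """Conjugate augmented update of alpha via Beta / CRT auxiliaries.

    The per-subject multiplicities (Z_i1, ..., Z_iK) of the G assignments
    are Dirichlet-multinomial; drawing q_i ~ Beta(G, alpha_0) and
    t_ik ~ CRT(Z_ik, alpha_k) restores conjugacy so that each
    alpha_k ~ Gamma(a0 + sum_i t_ik, rate b0 - sum_i log(1 - q_i)).
    """
    n, G = z.shape
    K = alpha.shape[0]
    a0 = 0.0
    for k in range(K):
        a0 += alpha[k]
    zmult = np.zeros(K, dtype=np.int64)
    tsum = np.zeros(K)
    neg_log1mq = 0.0
    for i in range(n):
        for k in range(K):
            zmult[k] = 0
        for g in range(G):
            zmult[z[i, g]] += 1
        q = np.random.beta(float(G), a0)
        if q > 1.0 - 1e-16:  # guard against numerical saturation at tiny alpha_0
            q = 1.0 - 1e-16
        neg_log1mq -= math.log1p(-q)
        for k in range(K):
            if zmult[k] > 0:
                tsum[k] += crt_draw(zmult[k], alpha[k])
    rate = b0_prior + neg_log1mq
    for k in range(K):
        alpha[k] = np.random.gamma(a0_prior + tsum[k], 1.0 / rate)


@njit(**_NJIT_KW)
def pointwise_loglik_kernel(y, s, G, loglam, pi, out):
    """Per-subject log p(y_i | theta) at the current state.

    log p(y_i) = sum_g log sum_k pi_{i,k} prod_{j: s_j=g} lambda_{j,y_ij,k}.
    """
    n, p = y.shape
    K = pi.shape[1]
    A = np.empty((n, G, K))
    for i in range(n):
        for g in range(G):
            for k in range(K):
                A[i, g, k] = math.log(pi[i, k])
    for j in range(p):
        g = s[j]
        for i in range(n):
            c = y[i, j]
            for k in range(K):
                A[i, g, k] += loglam[j, c, k]
    for i in range(n):
        tot = 0.0
        for g in range(G):
            mx = A[i, g, 0]
            for k in range(1, K):
                if A[i, g, k] > mx:
                    mx = A[i, g, k]
            se = 0.0
            for k in range(K):
                se += math.exp(A[i, g, k] - mx)
            tot += mx + math.log(se)
        out[i] = tot


@njit(**_NJIT_KW)
def col_logml_kernel(ycol, col, dj, K):
    """Dirichlet-multinomial log marginal of one item's data given a column,
    up to a constant shared by all columns (uniform table prior)."""
    counts = np.zeros((K, dj))
    for i in range(ycol.shape[0]):
        counts[col[i], ycol[i]] += 1.0
    out = 0.0
    for k in range(K):
        m = 0.0
        for c in range(dj):
            out += math.lgamma(1.0 + counts[k, c])
            m += counts[k, c]
        out -= math.lgamma(dj + m)
    return out


@njit(**_NJIT_KW)
def table_estimate_kernel(ycol, col, dj, K):
    """Posterior-mean table given a column: (1 + n_kc) / (d_j + m_k)."""
    counts = np.zeros((K, dj))
    for i in range(ycol.shape[0]):
        counts[col[i], ycol[i]] += 1.0
    for k in range(K):
        m = 0.0
        for c in range(dj):
            m += counts[k, c]
        for c in range(dj):
            counts[k, c] = (1.0 + counts[k, c]) / (dj + m)
    return counts


@njit(**_NJIT_KW)
def resample_y_kernel(y, d, z, s, lam):
    """Redraw the data given the current state (for joint-consistency tests)."""
    n, p = y.shape
    w = np.empty(lam.shape[1])
    for j in range(p):
        g = s[j]
        dj = d[j]
        for i in range(n):
            k = z[i, g]
            for c in range(dj):
                w[c] = lam[j, c, k]
            y[i, j] = _categorical_from_weights(w, dj)
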