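"""Sampler correctness: printed full conditionals on hand-checkable cases,
CRT auxiliary draws, concentration recovery, joint consistency (Geweke),
and chain bookkeeping."""

import numpy as np
import pytest

import gromm
from gromm import _kernels
from gromm.mcmc import (
    ChainState,
    MCMCConfig,
    initial_state,
    pointwise_loglik,
    resample_data,
    run_chain,
    s_full_conditional_probs,
    sample_crt,
    sweep,
    update_alpha_gibbs,
    update_alpha_mh,
    update_lambda,
    update_pi,
    update_z,
    z_full_conditional_probs,
)
from gromm.model_core import ItemDomain, ResponseMatrix


def _state(n, p, G, K, d=2, seed=0):
    """A valid hand-settable chain state with uniform-ish contents."""
    rng = np.random.default_rng(seed)
    lam = np.zeros((p, d, K))
    for j in range(p):
        lam[j] = rng.dirichlet(np.ones(d), size=K).T
    return ChainState(
        lam=lam, loglam=np.log(np.maximum(lam, 1e-300)),
        pi=rng.dirichlet(np.ones(K), size=n),
        z=rng.integers(0, K, size=(n, G)),
        s=rng.integers(0, G, size=p),
        xi=np.full(G, 1.0 / G),
        alpha=np.full(K, 0.5),
        d=np.full(p, d, dtype=np.int64), G=G)


def _data(state, rng=None):
    rng = rng or np.random.default_rng(1)
    y = rng.integers(0, state.d[0], size=(state.n, state.p))
    return ResponseMatrix(y, ItemDomain(state.d.tolist()))


class TestZConditional:
    def test_hand_checkable_odds(self):
        """pi=(0.3,0.7), one binary item with lambda_1=(0.9,0.2) at the
        observed category gives posterior (27/41, 14/41)."""
        st = _state(1, 1, 1, 2)
        st.pi = np.array([[0.3, 0.7]])
        st.lam[0] = np.array([[0.9, 0.2], [0.1, 0.8]])
        st.loglam = np.log(st.lam)
        st.s[:] = 0
        data = ResponseMatrix(np.array([[0]]), ItemDomain([2]))
        probs = z_full_conditional_probs(st, data, i=0, g=0)
        np.testing.assert_allclose(probs, [27 / 41, 14 / 41])

    def test_flat_tables_return_membership(self):
        st = _state(1, 2, 1, 3, d=2)
        st.lam[:, 0, :] = 0.5
        st.lam[:, 1, :] = 0.5
        st.loglam = np.log(st.lam)
        st.s[:] = 0
        st.pi = np.array([[0.2, 0.3, 0.5]])
        data = _data(st)
        np.testing.assert_allclose(
            z_full_conditional_probs(st, data, 0, 0), st.pi[0], atol=1e-12)

    def test_kernel_matches_probabilities(self):
        """Empirical frequencies of the compiled update match the directly
        evaluated conditional."""
        st = _state(1, 3, 1, 2, seed=3)
        data = _data(st)
        probs = z_full_conditional_probs(st, data, 0, 0)
        _kernels.seed_rng(77)
        draws = np.empty(4000, dtype=int)
        for t in range(draws.size):
            _kernels.update_z_kernel(data.y, st.z, st.s, st.loglam, st.pi)
            draws[t] = st.z[0, 0]
        freq = np.mean(draws == 0)
        se = np.sqrt(probs[0] * (1 - probs[0]) / draws.size)
        assert abs(freq - probs[0]) < 4 * se


class TestLambdaConditional:
    def test_conjugate_posterior_mean(self):
        """Counts (3,1,0) with d=3 give Dirichlet(4,2,1): mean (4/7,2/7,1/7)."""
        n, K = 4, 2
        st = _state(n, 1, 1, K, d=3)
        st.s[:] = 0
        st.z[:, 0] = 0  # all subjects use profile 0
        y = np.array([[0], [0], [0], [1]])
        data = ResponseMatrix(y, ItemDomain([3]))
        _kernels.seed_rng(5)
        acc = np.zeros(3)
        reps = 20000
        for _ in range(reps):
            update_lambda(st, data)
            acc += st.lam[0, :, 0]
        np.testing.assert_allclose(acc / reps, [4 / 7, 2 / 7, 1 / 7],
                                   atol=0.01)

    def test_unused_profile_reverts_to_prior(self):
        st = _state(50, 1, 1, 2, d=3)
        st.s[:] = 0
        st.z[:] = 0  # profile 1 never used -> Dirichlet(1,1,1), mean 1/3
        data = _data(st)
        _kernels.seed_rng(6)
        acc = np.zeros(3)
        for _ in range(5000):
            update_lambda(st, data)
            acc += st.lam[0, :, 1]
        np.testing.assert_allclose(acc / 5000, [1 / 3] * 3, atol=0.02)

    def test_columns_on_simplex(self):
        st = _state(30, 4, 2, 3, d=3, seed=9)
        data = _data(st)
        _kernels.seed_rng(7)
        update_lambda(st, data)
        np.testing.assert_allclose(st.lam.sum(axis=1), 1.0, atol=1e-12)


class TestPiConditional:
    def test_posterior_parameters(self):
        """z_i = (profile 0, profile 0), alpha=(0.4,0.5) -> Dirichlet(2.4,0.5)."""
        st = _state(1, 2, 2, 2)
        st.alpha = np.array([0.4, 0.5])
        st.z[0] = [0, 0]
        _kernels.seed_rng(8)
        acc = np.zeros(2)
        reps = 40000
        for _ in range(reps):
            update_pi(st, None)
            acc += st.pi[0]
        np.testing.assert_allclose(acc / reps, [2.4 / 2.9, 0.5 / 2.9],
                                   atol=0.005)
        assert st.pi[0].sum() == pytest.approx(1.0)


class TestGroupingConditional:
    def test_likelihood_cancels_when_assignments_agree(self):
        st = _state(5, 2, 3, 2, seed=11)
        st.z[:, :] = st.z[:, :1]  # identical columns
        st.xi = np.array([0.5, 0.3, 0.2])
        data = _data(st)
        probs = s_full_conditional_probs(st, data, j=0)
        np.testing.assert_allclose(probs, st.xi, atol=1e-12)

    def test_toy_case_direct_formula(self):
        st = _state(2, 2, 2, 2, seed=13)
        data = _data(st)
        for j in range(2):
            probs = s_full_conditional_probs(st, data, j)
            direct = np.array([
                st.xi[g] * np.prod([
                    st.lam[j, data.y[i, j], st.z[i, g]]
                    for i in range(2)]) for g in range(2)])
            np.testing.assert_allclose(probs, direct / direct.sum())

    def test_xi_posterior_counts(self):
        """When the likelihood pins every item to group 0, the weight
        update draws xi ~ Dirichlet(1 + p, 1): mean (7/8, 1/8) at p=6."""
        n, p = 12, 6
        st = _state(n, p, 2, 2, seed=15)
        pattern = np.arange(n) % 2
        eps = 1e-6
        st.lam[:, 0, 0] = 1 - eps
        st.lam[:, 1, 0] = eps
        st.lam[:, 0, 1] = eps
        st.lam[:, 1, 1] = 1 - eps
        st.loglam = np.log(st.lam)
        st.z[:, 0] = pattern        # matches the data under group 0
        st.z[:, 1] = 1 - pattern    # anti-matches under group 1
        data = ResponseMatrix(np.tile(pattern[:, None], (1, p)),
                              ItemDomain([2] * p))
        _kernels.seed_rng(9)
        acc = np.zeros(2)
        reps = 20000
        for _ in range(reps):
            st.xi[:] = 0.5
            _kernels.update_s_kernel(data.y, st.z, st.s, st.xi, st.loglam)
            assert (st.s == 0).all()
            acc += st.xi
        np.testing.assert_allclose(acc / reps, [7 / 8, 1 / 8], atol=0.01)


class TestCrt:
    def test_boundaries(self):
        assert sample_crt(0, 0.7, seed=1) == 0
        for s in range(20):
            assert sample_crt(1, 0.3, seed=s) == 1

    def test_domain_errors(self):
        with pytest.raises(ValueError, match="positive"):
            sample_crt(3, 0.0)
        with pytest.raises(ValueError, match=">= 0"):
            sample_crt(-1, 1.0)

    def test_analytic_mean(self):
        """E[t] = sum_{l=1}^m r/(r+l-1) for the table-count distribution."""
        m, r = 10, 0.5
        expected = sum(r / (r + l - 1) for l in range(1, m + 1))
        _kernels.seed_rng(10)
        draws = np.array([_kernels.crt_draw(m, r) for _ in range(40000)])
        assert draws.min() >= 1 and draws.max() <= m
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 4 * se


class TestAlphaUpdates:
    def test_mh_fixed_membership_recovery(self):
        """With memberships fixed at 1e4 i.i.d. Dirichlet(0.4,0.5,0.6) draws,
        iterating only the MH concentration move recovers the truth."""
        rng = np.random.default_rng(42)
        truth = np.array([0.4, 0.5, 0.6])
        st = _state(10_000, 1, 1, 3)
        st.pi = np.maximum(rng.dirichlet(truth, size=10_000), 1e-300)
        st.pi /= st.pi.sum(axis=1, keepdims=True)
        st.alpha = np.array([1.0, 1.0, 1.0])
        cfg = MCMCConfig(sigma_alpha=0.05, warmup=0)
        _kernels.seed_rng(11)
        draws = []
        for t in range(4000):
            update_alpha_mh(st, cfg)
            if t >= 1000:
                draws.append(st.alpha.copy())
        mean = np.mean(draws, axis=0)
        # posterior sd at n=1e4 is ~0.01 per coordinate
        np.testing.assert_allclose(mean, truth, atol=0.05)
        assert st.mh_proposals == 4000
        assert 0 < st.accept_count < 4000

    def test_gibbs_augmented_recovery(self):
        """The Beta/CRT/Gamma update targets the same posterior: with z
        fixed at truth-like multiplicities the concentrations stay in a
        plausible range and remain positive."""
        rng = np.random.default_rng(43)
        truth = np.array([0.4, 0.6])
        n, G = 2000, 6
        pi = rng.dirichlet(truth, size=n)
        z = (rng.random((n, G, 1)) > pi.cumsum(1)[:, None, :]).sum(2)
        st = _state(n, 1, G, 2)
        st.z = z
        st.alpha = np.array([1.0, 1.0])
        cfg = MCMCConfig(sampler="gibbs_augmented", a0=1.0, b0=1.0, warmup=0)
        _kernels.seed_rng(12)
        draws = []
        for t in range(3000):
            update_alpha_gibbs(st, cfg)
            if t >= 500:
                draws.append(st.alpha.copy())
        mean = np.mean(draws, axis=0)
        np.testing.assert_allclose(mean, truth, atol=0.12)
        assert (np.asarray(draws) > 0).all()


class TestGeweke:
    """Joint-distribution consistency: moments under (draw parameters from
    the prior, then data) match moments of a chain that alternates the full
    posterior sweep with re-simulating the data."""

    N, P, G, K = 3, 4, 2, 2

    def _config(self, sampler):
        return MCMCConfig(iterations=10, burn_in=5, thin=1, seed=0,
                          sampler=sampler, sigma_alpha=0.5,
                          split_merge_attempts=2, warmup=0)

    def _prior_draw(self, rng, cfg):
        domain = ItemDomain([2] * self.P)
        data = ResponseMatrix(np.zeros((self.N, self.P), dtype=np.int64),
                              domain)
        st = initial_state(data, self.G, self.K, cfg, rng)
        if cfg.sampler == "mh_within_gibbs":
            # the MH step targets the prior alpha0 ~ Gamma(a+K-1, b) in
            # alpha space (the printed density omits the (alpha0, eta)
            # Jacobian); match it exactly here
            a0 = rng.gamma(cfg.a_alpha + self.K - 1, 1.0 / cfg.b_alpha)
            st.alpha[:] = a0 * rng.dirichlet(np.ones(self.K))
        st.pi[:] = np.maximum(
            rng.dirichlet(np.maximum(st.alpha, 1e-12), size=self.N), 1e-300)
        st.pi /= st.pi.sum(axis=1, keepdims=True)
        cdf = np.cumsum(st.pi, axis=1)
        for g in range(self.G):
            st.z[:, g] = (rng.random((self.N, 1)) > cdf).sum(axis=1)
        return st, data

    def _stats(self, st, data):
        occ = np.bincount(st.s, minlength=self.G)
        return (st.alpha.sum(), st.lam[0, 0, 0], float(st.z.mean()),
                float(data.y.mean()), float(st.pi[:, 0].mean()),
                float(st.xi[0]), float((occ > 0).sum()))

    @pytest.mark.parametrize("sampler", ["mh_within_gibbs", "gibbs_augmented"])
    def test_marginal_vs_successive_conditional(self, sampler):
        cfg = self._config(sampler)
        rng = np.random.default_rng(2024)
        M = 12_000
        mc = np.empty((M, 7))
        for m in range(M):
            st, data = self._prior_draw(rng, cfg)
            _kernels.seed_rng(int(rng.integers(2**31 - 1)))
            resample_data(st, data)
            mc[m] = self._stats(st, data)

        rng2 = np.random.default_rng(2025)
        st, data = self._prior_draw(rng2, cfg)
        _kernels.seed_rng(int(rng2.integers(2**31 - 1)))
        S, thin = 120_000, 10
        sc = np.empty((S // thin, 7))
        for m in range(S):
            sweep(st, data, cfg, rng=rng2)
            resample_data(st, data)
            if m % thin == thin - 1:
                sc[m // thin] = self._stats(st, data)

        # conservative autocorrelation inflation for the chain variance
        for i in range(7):
            se = np.sqrt(mc[:, i].var() / M + sc[:, i].var() / len(sc) * 20)
            z = (mc[:, i].mean() - sc[:, i].mean()) / se
            assert abs(z) < 5.0, f"statistic {i} off: z={z:.2f}"


class TestRunChain:
    def test_draw_count_and_shapes(self):
        truth = gromm.paper_scenario(2, 30, 6)
        ds = gromm.sample_dataset(truth, 60, 4)
        cfg = MCMCConfig(iterations=300, burn_in=100, thin=4, seed=1,
                         warmup=50, store_pi=True, store_z=True)
        samples = run_chain(ds.responses, 6, 2, cfg)
        assert samples.n_draws == 50
        assert samples.lam.shape == (50, 30, 3, 2)
        assert samples.loglik.shape == (50, 60)
        assert samples.pi.shape == (50, 60, 2)
        assert samples.z.shape == (50, 60, 6)
        assert samples.acceptance_rate is not None
        # grouping draws stay in range and xi rows on the simplex
        assert samples.s.min() >= 0 and samples.s.max() < 6
        np.testing.assert_allclose(samples.xi.sum(axis=1), 1.0, atol=1e-9)

    def test_determinism(self):
        truth = gromm.paper_scenario(2, 30, 6)
        ds = gromm.sample_dataset(truth, 50, 4)
        cfg = MCMCConfig(iterations=200, burn_in=100, thin=2, seed=9,
                         warmup=40)
        a = run_chain(ds.responses, 6, 2, cfg)
        b = run_chain(ds.responses, 6, 2, cfg)
        np.testing.assert_array_equal(a.s, b.s)
        np.testing.assert_allclose(a.lam, b.lam)
        np.testing.assert_allclose(a.alpha, b.alpha)
        np.testing.assert_allclose(a.loglik, b.loglik)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(iterations=100, burn_in=200)
        with pytest.raises(ValueError):
            MCMCConfig(sampler="vanilla")
        with pytest.raises(ValueError):
            MCMCConfig(sigma_alpha=0.0)

    def test_pointwise_loglik_matches_model_core(self):
        from gromm.model_core import log_pmf_given_membership
        truth = gromm.paper_scenario(2, 30, 6)
        ds = gromm.sample_dataset(truth, 20, 4)
        cfg = MCMCConfig(iterations=20, burn_in=10, thin=1, seed=2, warmup=5)
        rng = np.random.default_rng(0)
        st = initial_state(ds.responses, 6, 2, cfg, rng)
        ll = pointwise_loglik(st, ds.responses)
        expected = [log_pmf_given_membership(
            ds.responses.y[i], st.grouping(), st.tables(), st.pi[i])
            for i in range(20)]
        np.testing.assert_allclose(ll, expected, rtol=1e-10)
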