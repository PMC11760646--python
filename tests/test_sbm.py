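"""Likelihood, full conditionals, beta updates and the Gibbs sampler."""

import numpy as np
import pytest

from sbmmrf import (
    GibbsConfig,
    MRFPrior,
    conditional_z_probs,
    edge_counts,
    log_likelihood,
    mrf_conditional_logits,
    relabel_by_intra_prob,
    run_gibbs,
    sample_omega,
)
from sbmmrf.metrics import ari
from sbmmrf.sbm import block_log_likelihood, log_unnormalized_posterior


def _random_graph(rng, p, density=0.3):
    A = np.triu(rng.random((p, p)) < density, k=1)
    return (A | A.T).astype(np.int8)


class TestEdgeCounts:
    def test_complete_graph_single_community(self):
        A = 1 - np.eye(4, dtype=np.int8)
        M, N = edge_counts(A, np.zeros(4, dtype=int), 1)
        assert M[0, 0] == 6 and N[0, 0] == 6

    def test_empty_graph(self, rng):
        z = rng.integers(0, 3, 10)
        M, N = edge_counts(np.zeros((10, 10), np.int8), z, 3)
        assert M.sum() == 0
        n_k = np.bincount(z, minlength=3)
        np.testing.assert_array_equal(np.diag(N), n_k * (n_k - 1) // 2)

    def test_matches_pair_enumeration(self, rng):
        p, K = 30, 4
        A = _random_graph(rng, p)
        z = rng.integers(0, K, p)
        M, N = edge_counts(A, z, K)
        M_bf = np.zeros((K, K), np.int64)
        N_bf = np.zeros((K, K), np.int64)
        for j in range(p):
            for jj in range(j + 1, p):
                k, kk = sorted((z[j], z[jj]))
                N_bf[k, kk] += 1
                if A[j, jj]:
                    M_bf[k, kk] += 1
        M_bf = np.triu(M_bf) + np.triu(M_bf, 1).T
        N_bf = np.triu(N_bf) + np.triu(N_bf, 1).T
        np.testing.assert_array_equal(M, M_bf)
        np.testing.assert_array_equal(N, N_bf)

    def test_sufficient_statistic_conservation(self, rng):
        p, K = 25, 3
        A = _random_graph(rng, p)
        z = rng.integers(0, K, p)
        M, N = edge_counts(A, z, K)
        iu = np.triu_indices(K)
        assert N[iu].sum() == p * (p - 1) // 2
        assert M[iu].sum() == A.sum() // 2


class TestLogLikelihood:
    def test_half_omega_closed_form(self, rng):
        p, K = 12, 3
        A = _random_graph(rng, p)
        z = rng.integers(0, K, p)
        omega = np.full((K, K), 0.5)
        np.testing.assert_allclose(
            log_likelihood(A, z, omega), -(p * (p - 1) / 2) * np.log(2)
        )

    def test_boundary_zero_log_zero(self):
        A = 1 - np.eye(3, dtype=np.int8)
        assert log_likelihood(A, np.zeros(3, int), np.array([[1.0]])) == 0.0
        # impossible block: omega=0 with observed edges
        assert log_likelihood(A, np.zeros(3, int), np.array([[0.0]])) == -np.inf

    def test_matches_per_pair_bernoulli_sum(self, rng):
        p, K = 20, 3
        A = _random_graph(rng, p)
        z = rng.integers(0, K, p)
        omega = rng.uniform(0.05, 0.95, (K, K))
        omega = (omega + omega.T) / 2
        expected = 0.0
        for j in range(p):
            for jj in range(j + 1, p):
                w = omega[z[j], z[jj]]
                expected += np.log(w) if A[j, jj] else np.log1p(-w)
        np.testing.assert_allclose(log_likelihood(A, z, omega), expected, atol=1e-9)


class TestMRFConditional:
    def test_d_zero_reduces_to_base_rates(self, rng):
        K, p = 4, 10
        Q = _random_graph(rng, p, 0.5)
        z = rng.integers(0, K, p)
        logits = mrf_conditional_logits(3, z, Q, MRFPrior(d=0.0), K)
        np.testing.assert_allclose(logits, np.full(K, -np.log(K)))

    def test_no_neighbors_gives_base_rates(self, rng):
        K, p = 3, 8
        z = rng.integers(0, K, p)
        logits = mrf_conditional_logits(0, z, np.zeros((p, p), np.int8),
                                        MRFPrior(d=2.0), K)
        np.testing.assert_allclose(logits, np.full(K, -np.log(K)))

    def test_three_neighbors_in_one_community(self):
        K, p = 3, 6
        Q = np.zeros((p, p), np.int8)
        for jj in (1, 2, 3):
            Q[0, jj] = Q[jj, 0] = 1
        z = np.array([0, 1, 1, 1, 2, 2])
        logits = mrf_conditional_logits(0, z, Q, MRFPrior(d=1.0), K)
        assert logits[1] - logits[0] == pytest.approx(3.0)
        assert logits[1] - logits[2] == pytest.approx(3.0)


class TestConditionalZProbs:
    def test_likelihood_dominance_sign(self):
        # star node 0 connected only to community-0 nodes
        p = 7
        A = np.zeros((p, p), np.int8)
        for jj in range(1, 4):
            A[0, jj] = A[jj, 0] = 1
        z = np.array([0, 0, 0, 0, 1, 1, 1])
        omega = np.array([[0.9, 0.1], [0.1, 0.9]])
        xi = conditional_z_probs(0, z, omega, A, np.zeros((p, p), np.int8),
                                 MRFPrior(d=0.0))
        assert xi[0] > xi[1]

    def test_symmetric_configuration_uniform(self):
        p, K = 6, 3
        omega = np.full((K, K), 0.4)
        xi = conditional_z_probs(0, np.zeros(p, int), omega,
                                 np.zeros((p, p), np.int8),
                                 np.zeros((p, p), np.int8), MRFPrior(d=0.0))
        np.testing.assert_allclose(xi, 1 / 3)

    def test_matches_exhaustive_relabeling_oracle(self, rng):
        p, K = 8, 2
        for _ in range(20):
            A = _random_graph(rng, p, 0.4)
            Q = _random_graph(rng, p, 0.3)
            z = rng.integers(0, K, p)
            omega = rng.uniform(0.05, 0.95, (K, K))
            omega = (omega + omega.T) / 2
            prior = MRFPrior(d=float(rng.uniform(0, 2)))
            j = int(rng.integers(p))
            logits = np.empty(K)
            for k in range(K):
                zc = z.copy()
                zc[j] = k
                logits[k] = (log_likelihood(A, zc, omega)
                             + mrf_conditional_logits(j, z, Q, prior, K)[k])
            logits -= logits.max()
            want = np.exp(logits) / np.exp(logits).sum()
            got = conditional_z_probs(j, z, omega, A, Q, prior)
            np.testing.assert_allclose(got, want, atol=1e-10)
            assert got.sum() == pytest.approx(1.0)


class TestSampleOmega:
    def test_posterior_mean_and_variance(self):
        rng = np.random.default_rng(5)
        M = np.array([[6]])
        N = np.array([[10]])
        draws = np.array([sample_omega(M, N, rng)[0, 0] for _ in range(20000)])
        a, b = 7, 5
        mean = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert draws.mean() == pytest.approx(mean, abs=4 * np.sqrt(var / 20000))
        assert draws.var() == pytest.approx(var, rel=0.1)

    def test_empty_block_draws_from_prior(self):
        rng = np.random.default_rng(6)
        M = np.zeros((1, 1), int)
        N = np.zeros((1, 1), int)
        draws = np.array([sample_omega(M, N, rng)[0, 0] for _ in range(5000)])
        assert draws.mean() == pytest.approx(0.5, abs=0.02)  # Beta(1,1) = U(0,1)
        assert draws.min() > 0 and draws.max() < 1

    def test_output_symmetric(self, rng):
        M = np.array([[3, 1, 0], [1, 2, 2], [0, 2, 5]])
        N = M + 4
        omega = sample_omega(M, N, rng)
        np.testing.assert_array_equal(omega, omega.T)


class TestRelabel:
    def test_sort_example(self):
        omega = np.diag([0.2, 0.9, 0.5])
        z = np.array([0, 1, 2, 2])
        z_new, omega_new, perm = relabel_by_intra_prob(z, omega)
        np.testing.assert_array_equal(perm, [1, 2, 0])
        np.testing.assert_allclose(np.diag(omega_new), [0.9, 0.5, 0.2])
        np.testing.assert_array_equal(z_new, [2, 0, 1, 1])

    def test_already_sorted_is_identity(self):
        omega = np.diag([0.9, 0.5, 0.2])
        z = np.array([0, 1, 2])
        z_new, omega_new, perm = relabel_by_intra_prob(z, omega)
        np.testing.assert_array_equal(perm, [0, 1, 2])
        np.testing.assert_array_equal(z_new, z)

    def test_log_likelihood_invariant(self, rng):
        p, K = 15, 4
        A = _random_graph(rng, p)
        z = rng.integers(0, K, p)
        omega = rng.uniform(0.1, 0.9, (K, K))
        omega = (omega + omega.T) / 2
        before = log_likelihood(A, z, omega)
        z_new, omega_new, _ = relabel_by_intra_prob(z, omega)
        np.testing.assert_allclose(log_likelihood(A, z_new, omega_new), before,
                                   atol=1e-9)


class TestRunGibbs:
    def test_k1_reduces_to_beta_sampling(self, rng):
        p = 10
        A = _random_graph(rng, p, 0.4)
        n_edges = A.sum() // 2
        chain = run_gibbs(A, np.zeros((p, p), np.int8), K=1,
                          config=GibbsConfig(n_iter=4000, seed=3))
        assert np.all(chain.z_samples == 0)
        expected = (n_edges + 1) / (p * (p - 1) / 2 + 2)
        got = chain.omega_samples[2000:, 0, 0].mean()
        assert got == pytest.approx(expected, abs=0.01)

    def test_two_cliques_recovered(self, two_cliques):
        net, z_true = two_cliques
        Q0 = np.zeros((20, 20), np.int8)
        chain = run_gibbs(net, Q0, K=2, prior=MRFPrior(d=0.0),
                          config=GibbsConfig(n_iter=500, seed=4))
        from sbmmrf import map_estimate

        z_map, _ = map_estimate(chain)
        assert ari(z_true, z_map) == 1.0

    def test_aligned_taxonomy_preserves_recovery(self, two_cliques):
        net, z_true = two_cliques
        Q = (z_true[:, None] == z_true[None, :]).astype(np.int8)
        np.fill_diagonal(Q, 0)
        chain = run_gibbs(net, Q, K=2, prior=MRFPrior(d=1.0),
                          config=GibbsConfig(n_iter=500, seed=4))
        from sbmmrf import map_estimate

        z_map, _ = map_estimate(chain)
        assert ari(z_true, z_map) == 1.0

    def test_bit_identical_reproducibility(self, two_cliques):
        net, _ = two_cliques
        Q = np.zeros((20, 20), np.int8)
        cfg = GibbsConfig(n_iter=100, seed=7)
        c1 = run_gibbs(net, Q, 2, config=cfg)
        c2 = run_gibbs(net, Q, 2, config=GibbsConfig(n_iter=100, seed=7))
        np.testing.assert_array_equal(c1.z_samples, c2.z_samples)
        np.testing.assert_array_equal(c1.omega_samples, c2.omega_samples)
        np.testing.assert_array_equal(c1.log_post, c2.log_post)

    def test_chain_state_validity(self, rng, two_cliques):
        net, _ = two_cliques
        Q = _random_graph(rng, 20, 0.2)
        chain = run_gibbs(net, Q, 3, prior=MRFPrior(d=0.5),
                          config=GibbsConfig(n_iter=80, seed=9))
        assert np.all((chain.z_samples >= 0) & (chain.z_samples < 3))
        assert np.all((chain.omega_samples > 0) & (chain.omega_samples < 1))
        np.testing.assert_array_equal(chain.omega_samples,
                                      chain.omega_samples.transpose(0, 2, 1))
        assert np.all(np.isfinite(chain.log_post))
        # relabeling keeps intra-block probabilities sorted descending
        diags = np.diagonal(chain.omega_samples, axis1=1, axis2=2)
        assert np.all(np.diff(diags, axis=1) <= 1e-12)

    def test_stored_log_post_matches_rescoring(self, rng, two_cliques):
        net, _ = two_cliques
        Q = _random_graph(rng, 20, 0.2)
        prior = MRFPrior(d=1.0)
        chain = run_gibbs(net, Q, 2, prior=prior,
                          config=GibbsConfig(n_iter=60, seed=2))
        for t in range(chain.burn_in, 60, 7):
            lp = log_unnormalized_posterior(net, Q, chain.z_samples[t],
                                            chain.omega_samples[t], prior)
            assert lp == pytest.approx(chain.log_post[t], abs=1e-8)


def test_block_log_likelihood_agrees_with_wrapper(rng):
    p, K = 15, 3
    A = _random_graph(rng, p)
    z = rng.integers(0, K, p)
    omega = rng.uniform(0.1, 0.9, (K, K))
    omega = (omega + omega.T) / 2
    M, N = edge_counts(A, z, K)
    np.testing.assert_allclose(block_log_likelihood(M, N, omega),
                               log_likelihood(A, z, omega))
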