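import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import digamma, gammaln

from taxatopics import CountTable, e_step, elbo, estimate_alpha, fit_lda
from taxatopics.synthetic_data import evaluate_recovery, generate_cohort, generate_topics


def _table(counts):
    counts = np.asarray(counts, dtype=float)
    return CountTable(
        counts,
        [f"s{i}" for i in range(counts.shape[0])],
        [f"g{j}" for j in range(counts.shape[1])],
    )


# ---------------------------------------------------------------------------
# e_step
# ---------------------------------------------------------------------------


class TestEStep:
    def test_degenerate_beta_forces_assignment(self):
        res = e_step(np.array([10.0, 0.0]), np.array([[1.0, 0.0], [0.0, 1.0]]), alpha=1.0)
        np.testing.assert_allclose(res.gamma_d, [11.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(res.phi_d[0], [1.0, 0.0], atol=1e-12)

    def test_identical_rows_symmetric_phi(self):
        beta = np.array([[0.2, 0.3, 0.5], [0.2, 0.3, 0.5]])
        res = e_step(np.array([4.0, 1.0, 2.0]), beta, alpha=0.7)
        np.testing.assert_allclose(res.phi_d, 0.5, atol=1e-12)

    def test_matches_scalar_fixed_point_oracle(self):
        # independent oracle: plain python loops over the same fixed point
        beta = np.array([[0.7, 0.2, 0.1], [0.1, 0.2, 0.7]])
        doc = np.array([3.0, 1.0, 2.0])
        alpha = 0.5
        K, V = 2, 3
        gamma = [alpha + doc.sum() / K] * K
        for _ in range(10_000):
            new = [alpha] * K
            dg_sum = digamma(sum(gamma))
            for v in range(V):
                weights = [beta[k][v] * np.exp(digamma(gamma[k]) - dg_sum) for k in range(K)]
                s = sum(weights)
                for k in range(K):
                    new[k] += doc[v] * weights[k] / s
            if max(abs(a - b) for a, b in zip(new, gamma)) < 1e-14:
                gamma = new
                break
            gamma = new
        res = e_step(doc, beta, alpha, tol=1e-14, max_iter=10_000)
        np.testing.assert_allclose(res.gamma_d, gamma, atol=1e-10)

    def test_phi_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        beta = rng.dirichlet(np.ones(6), size=3)
        res = e_step(rng.integers(0, 9, 6).astype(float), beta, alpha=0.4)
        np.testing.assert_allclose(res.phi_d.sum(axis=1), 1.0, atol=1e-10)

    def test_gamma_at_least_alpha(self):
        rng = np.random.default_rng(1)
        beta = rng.dirichlet(np.ones(5), size=4)
        res = e_step(rng.integers(0, 20, 5).astype(float), beta, alpha=0.3)
        assert np.all(res.gamma_d >= 0.3 - 1e-12)

    def test_zero_probability_term_errors(self):
        beta = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="zero probability"):
            e_step(np.array([1.0, 5.0]), beta, alpha=1.0)


# ---------------------------------------------------------------------------
# estimate_alpha
# ---------------------------------------------------------------------------


class TestEstimateAlpha:
    def test_stationary_point_matches_root_finder(self):
        # gammas all equal (c, ..., c): stationary alpha solves
        # digamma(K a) - digamma(a) = digamma(K c) - digamma(c)
        K, c, D = 4, 2.5, 12
        gammas = np.full((D, K), c)
        target = digamma(K * c) - digamma(c)
        root = brentq(lambda a: digamma(K * a) - digamma(a) - target, 1e-6, 1e3)
        est = estimate_alpha(gammas, alpha=1.0)
        assert est == pytest.approx(root, abs=1e-8)

    def test_single_document_finite(self):
        est = estimate_alpha(np.array([[0.4, 9.0, 0.2]]), alpha=1.0)
        assert np.isfinite(est) and est > 0

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        gammas = rng.gamma(2.0, 1.0, (10, 3))
        assert estimate_alpha(gammas, 0.7) == estimate_alpha(gammas, 0.7)

    def test_never_decreases_objective(self):
        rng = np.random.default_rng(3)
        gammas = rng.gamma(1.5, 2.0, (8, 5))
        D, K = gammas.shape
        s = float((digamma(gammas) - digamma(gammas.sum(axis=1))[:, None]).sum())

        def objective(a):
            return D * (gammaln(K * a) - K * gammaln(a)) + (a - 1.0) * s

        for a0 in (0.01, 0.5, 1.0, 10.0):
            assert objective(estimate_alpha(gammas, a0)) >= objective(a0) - 1e-9

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            estimate_alpha(np.array([[1.0, -1.0]]), 1.0)
        with pytest.raises(ValueError):
            estimate_alpha(np.ones((2, 2)), 0.0)


# ---------------------------------------------------------------------------
# fit_lda
# ---------------------------------------------------------------------------


def _two_block_table(seed=0, D=30, half=6, reads=500):
    """Samples containing exactly one of two disjoint term blocks."""
    rng = np.random.default_rng(seed)
    V = 2 * half
    counts = np.zeros((D, V))
    for d in range(D):
        block = d % 2
        p = np.zeros(V)
        p[block * half : (block + 1) * half] = rng.dirichlet(np.ones(half))
        counts[d] = rng.multinomial(reads, p)
    return _table(counts)


class TestFitLda:
    def test_two_disjoint_blocks_recovered(self):
        table = _two_block_table()
        model = fit_lda(table, K=2, seed=1, n_starts=3)
        half = table.n_features // 2
        block_mass = np.sort(
            [model.beta[:, :half].sum(axis=1).max(), model.beta[:, half:].sum(axis=1).max()]
        )
        assert np.all(block_mass >= 0.99)

    def test_k1_degeneracy_pooled_frequencies(self):
        table = _table([[5.0, 3.0, 2.0], [1.0, 1.0, 8.0]])
        model = fit_lda(table, K=1, seed=0, eta=0.0, estimate_alpha=False)
        pooled = table.counts.sum(axis=0) / table.counts.sum()
        np.testing.assert_allclose(model.beta[0], pooled, atol=1e-12)
        np.testing.assert_allclose(model.gamma_norm, 1.0, atol=1e-12)

    def test_same_seed_bitwise_identical(self, random_table):
        m1 = fit_lda(random_table, K=3, seed=11, n_starts=2)
        m2 = fit_lda(random_table, K=3, seed=11, n_starts=2)
        assert np.array_equal(m1.beta, m2.beta)
        assert np.array_equal(m1.gamma_norm, m2.gamma_norm)
        assert m1.alpha == m2.alpha

    def test_row_normalization(self, random_table):
        model = fit_lda(random_table, K=4, seed=3)
        np.testing.assert_allclose(model.beta.sum(axis=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(model.gamma_norm.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(model.beta >= 0) and np.all(model.gamma_norm >= 0)

    def test_elbo_monotone(self, random_table):
        model = fit_lda(random_table, K=3, seed=5)
        assert np.all(np.diff(model.elbo_trace) >= -1e-6)

    def test_k_out_of_range(self, random_table):
        with pytest.raises(ValueError, match="out of range"):
            fit_lda(random_table, K=25, seed=0)

    def test_zero_total_sample_rejected(self):
        t = _table([[0.0, 0.0], [1.0, 2.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="zero total"):
            fit_lda(t, K=1, seed=0)

    def test_nonconvergence_warns_not_errors(self, random_table):
        with pytest.warns(RuntimeWarning, match="did not converge"):
            model = fit_lda(random_table, K=3, seed=0, max_iter=3, tol=1e-12)
        assert not model.converged

    def test_fractional_counts_accepted(self, random_table):
        t = CountTable(
            random_table.counts * 0.75,
            random_table.sample_ids,
            random_table.feature_ids,
        )
        model = fit_lda(t, K=2, seed=0)
        assert np.all(np.isfinite(model.beta))

    def test_sample_permutation_equivariance(self, random_table):
        m = fit_lda(random_table, K=3, seed=9)
        perm = np.random.default_rng(0).permutation(random_table.n_samples)
        shuffled = CountTable(
            random_table.counts[perm],
            [random_table.sample_ids[i] for i in perm],
            random_table.feature_ids,
        )
        m2 = fit_lda(shuffled, K=3, seed=9)
        np.testing.assert_allclose(m2.gamma_norm, m.gamma_norm[perm], atol=1e-8)

    def test_vocab_permutation_equivariance(self, random_table):
        rng = np.random.default_rng(4)
        beta0 = rng.dirichlet(np.ones(random_table.n_features), size=3)
        m = fit_lda(random_table, K=3, seed=0, beta_init=beta0)
        perm = rng.permutation(random_table.n_features)
        permuted = CountTable(
            random_table.counts[:, perm],
            random_table.sample_ids,
            [random_table.feature_ids[j] for j in perm],
        )
        m2 = fit_lda(permuted, K=3, seed=0, beta_init=beta0[:, perm])
        np.testing.assert_allclose(m2.beta, m.beta[:, perm], atol=1e-8)

    def test_recovery_on_well_separated_topics(self):
        beta = generate_topics(4, 60, 8, dominance=0.92, seed=21)
        alpha = {"all": np.full(4, 0.5)}
        table, truth = generate_cohort(beta, alpha, {"all": 60}, seed=22)
        model = fit_lda(table, K=4, seed=1, n_starts=3)
        report = evaluate_recovery(model, truth)
        assert np.all(report.matched_cosines >= 0.95)


class TestElbo:
    def test_recompute_matches_trace(self, random_table):
        model = fit_lda(random_table, K=3, seed=7)
        assert elbo(model, random_table) == pytest.approx(model.elbo_trace[-1], abs=1e-6)

    def test_k1_closed_form(self):
        # K=1, eta=0: objective is the (weighted) multinomial log likelihood
        table = _table([[4.0, 6.0], [3.0, 7.0]])
        model = fit_lda(table, K=1, seed=0, eta=0.0, estimate_alpha=False)
        pooled = table.counts.sum(axis=0) / table.counts.sum()
        expected = float((table.counts * np.log(pooled)).sum())
        assert elbo(model, table) == pytest.approx(expected, abs=1e-8)

    def test_all_zero_sample_contributes_nothing(self, random_table):
        model = fit_lda(random_table, K=3, seed=2)
        base = elbo(model, random_table)
        augmented = CountTable(
            np.vstack([random_table.counts, np.zeros(random_table.n_features)]),
            random_table.sample_ids + ["empty"],
            random_table.feature_ids,
        )
        assert elbo(model, augmented) == pytest.approx(base, abs=1e-8)

    def test_vocab_mismatch_error(self, random_table):
        model = fit_lda(random_table, K=2, seed=0)
        other = _table(np.ones((3, 4)))
        with pytest.raises(ValueError, match="vocab"):
            elbo(model, other)


class TestReferenceImplementation:
    def test_agreement_with_sklearn_variational_lda(self):
        from sklearn.decomposition import LatentDirichletAllocation

        beta = generate_topics(3, 30, 6, dominance=0.95, seed=31)
        alpha = {"all": np.full(3, 0.4)}
        table, _ = generate_cohort(
            beta, alpha, {"all": 20}, depth_log_mean=np.log(5e3), seed=32
        )
        ours = fit_lda(table, K=3, seed=1, n_starts=3)
        ref = LatentDirichletAllocation(
            n_components=3, random_state=0, max_iter=300, learning_method="batch"
        ).fit(table.counts)
        ref_beta = ref.components_ / ref.components_.sum(axis=1, keepdims=True)
        cos = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                cos[i, j] = ours.beta[i] @ ref_beta[j] / (
                    np.linalg.norm(ours.beta[i]) * np.linalg.norm(ref_beta[j])
                )
        # greedy one-to-one matching
        matched = []
        work = cos.copy()
        for _ in range(3):
            i, j = np.unravel_index(np.argmax(work), work.shape)
            matched.append(cos[i, j])
            work[i, :] = -1
            work[:, j] = -1
        assert min(matched) >= 0.99
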