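"""Feature embeddings, Fisher scores and kernel construction."""

import numpy as np
import pytest

from hmmkernels.baselines import gaussian_kl
from hmmkernels.hmm import HMMParams, fit_group_hmm, log_likelihood, sample_hmm
from hmmkernels.kernels import (
    FeatureSet,
    devectorise_params,
    fisher_kernel,
    fisher_score,
    fisher_scores,
    gaussian_kernel,
    kl_hmm,
    kl_kernel,
    linear_kernel,
    naive_features,
    naive_kernel,
    normalise_features,
    subset_features,
    vectorise_params,
    whiten_scores,
)
from hmmkernels.simulate import make_base_hmm


def _random_hmm(K, M, seed):
    return make_base_hmm(K, M, np.random.default_rng(seed))


class TestVectorisation:
    def test_block_sizes_k6_m50(self):
        p = _random_hmm(6, 50, 0)
        vec, bi = vectorise_params(p)
        state = (bi["mu"].stop - bi["mu"].start) + (bi["sigma"].stop - bi["sigma"].start)
        transition = (bi["pi"].stop - bi["pi"].start) + (bi["A"].stop - bi["A"].start)
        assert state == 15_300
        assert transition == 42
        assert vec.size == 15_342

    def test_roundtrip_exact(self):
        p = _random_hmm(3, 4, 1)
        vec, _ = vectorise_params(p)
        q = devectorise_params(vec, 3, 4)
        assert np.array_equal(q.pi, p.pi) and np.array_equal(q.A, p.A)
        assert np.array_equal(q.mu, p.mu) and np.array_equal(q.sigma, p.sigma)

    def test_minimal_model_length(self):
        p = HMMParams(np.array([1.0]), np.array([[1.0]]),
                      np.array([[0.0]]), np.array([[[1.0]]]))
        vec, _ = vectorise_params(p)
        assert vec.size == 4


class TestNaiveKernels:
    def test_linear_matches_double_loop(self, rng):
        X = rng.standard_normal((6, 11))
        fs = FeatureSet(X, {"mu": slice(0, 11)})
        K = naive_kernel(fs, "linear")
        loop = np.array([[float(np.dot(X[i], X[j])) for j in range(6)] for i in range(6)])
        assert np.allclose(K, loop, atol=1e-10)

    def test_identical_subjects(self, rng):
        X = rng.standard_normal((3, 5))
        X[1] = X[0]
        fs = FeatureSet(X, {"mu": slice(0, 5)})
        Kg = naive_kernel(fs, "gaussian", tau=1.0)
        assert Kg[0, 1] == pytest.approx(1.0)
        Kl = naive_kernel(fs, "linear")
        assert Kl[0, 1] == pytest.approx(np.sum(X[0] ** 2))

    def test_gaussian_width_limit(self, rng):
        X = rng.standard_normal((4, 3))
        fs = FeatureSet(X, {"mu": slice(0, 3)})
        K = naive_kernel(fs, "gaussian", tau=1e9)
        assert np.all(K > 0.999999)

    def test_gaussian_requires_tau(self, rng):
        fs = FeatureSet(rng.standard_normal((3, 2)), {"mu": slice(0, 2)})
        with pytest.raises(ValueError, match="tau"):
            naive_kernel(fs, "gaussian")

    def test_gaussian_unit_diagonal_and_range(self, rng):
        fs = FeatureSet(rng.standard_normal((5, 7)), {"mu": slice(0, 7)})
        K = gaussian_kernel(fs, tau=1.0)
        assert np.allclose(np.diag(K), 1.0)
        assert np.all((K > 0) & (K <= 1.0 + 1e-12))

    def test_linear_kernel_psd(self, rng):
        fs = FeatureSet(rng.standard_normal((8, 4)), {"mu": slice(0, 4)})
        w = np.linalg.eigvalsh(linear_kernel(fs))
        assert w.min() >= -1e-8 * max(w.max(), 1.0)


class TestNormaliseFeatures:
    def test_full_sample_statistics(self, rng):
        fs = FeatureSet(rng.standard_normal((10, 4)) * 3 + 1, {"mu": slice(0, 4)})
        z = normalise_features(fs)
        assert np.allclose(z.values.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(z.values.std(axis=0), 1.0, atol=1e-12)

    def test_constant_column_zeroed(self, rng):
        X = rng.standard_normal((6, 3))
        X[:, 1] = 2.5
        z = normalise_features(FeatureSet(X, {"mu": slice(0, 3)}))
        assert np.all(z.values[:, 1] == 0.0)

    def test_training_fold_statistics_applied_to_test(self, rng):
        X = rng.standard_normal((8, 3)) + 5.0
        train = np.arange(5)
        z = normalise_features(FeatureSet(X, {"mu": slice(0, 3)}), stats_from=train)
        assert np.allclose(z.values[train].mean(axis=0), 0.0, atol=1e-12)
        # test rows use training statistics, not their own
        assert not np.allclose(z.values[5:].mean(axis=0), 0.0, atol=1e-3)


def _block_relative_errors(group, x, transition_grad):
    """Finite-difference oracle per block, in the gradient's parameterisation."""
    g, bi = fisher_score(group, x, transition_grad=transition_grad)
    K, M = group.K, group.M
    eps = 1e-5
    out = {}

    def ll(p):
        return log_likelihood(p, x)

    if transition_grad == "softmax":
        zp0, zA0 = np.log(group.pi), np.log(group.A)

        def from_logits(zp, zA):
            pi = np.exp(zp - zp.max())
            pi /= pi.sum()
            A = np.exp(zA - zA.max(axis=1, keepdims=True))
            A /= A.sum(axis=1, keepdims=True)
            return HMMParams(pi, A, group.mu, group.sigma)

        fd_pi = np.zeros(K)
        for k in range(K):
            zp = zp0.copy()
            zp[k] += eps
            up = ll(from_logits(zp, zA0))
            zp[k] -= 2 * eps
            dn = ll(from_logits(zp, zA0))
            fd_pi[k] = (up - dn) / (2 * eps)
        fd_A = np.zeros((K, K))
        for j in range(K):
            for k in range(K):
                zA = zA0.copy()
                zA[j, k] += eps
                up = ll(from_logits(zp0, zA))
                zA[j, k] -= 2 * eps
                dn = ll(from_logits(zp0, zA))
                fd_A[j, k] = (up - dn) / (2 * eps)
    else:
        fd_pi = np.zeros(K)
        for k in range(K):
            pp, pm = group.copy(), group.copy()
            pp.pi[k] += eps
            pm.pi[k] -= eps
            fd_pi[k] = (ll(pp) - ll(pm)) / (2 * eps)
        fd_A = np.zeros((K, K))
        for j in range(K):
            for k in range(K):
                pp, pm = group.copy(), group.copy()
                pp.A[j, k] += eps
                pm.A[j, k] -= eps
                fd_A[j, k] = (ll(pp) - ll(pm)) / (2 * eps)

    out["pi"] = np.abs(fd_pi - g[bi["pi"]]).max() / max(np.abs(fd_pi).max(), 1e-10)
    out["A"] = np.abs(fd_A.ravel() - g[bi["A"]]).max() / max(np.abs(fd_A).max(), 1e-10)

    fd_mu = np.zeros((K, M))
    for k in range(K):
        for i in range(M):
            pp, pm = group.copy(), group.copy()
            pp.mu[k, i] += eps
            pm.mu[k, i] -= eps
            fd_mu[k, i] = (ll(pp) - ll(pm)) / (2 * eps)
    out["mu"] = np.abs(fd_mu.ravel() - g[bi["mu"]]).max() / np.abs(fd_mu).max()

    # symmetric perturbations: the FD value equals G_ij + G_ji off-diagonal
    gs = g[bi["sigma"]].reshape(K, M, M)
    errs, mags = [], []
    for k in range(K):
        for i in range(M):
            for j in range(i, M):
                pp, pm = group.copy(), group.copy()
                pp.sigma[k, i, j] += eps
                pm.sigma[k, i, j] -= eps
                if i != j:
                    pp.sigma[k, j, i] += eps
                    pm.sigma[k, j, i] -= eps
                fd = (ll(pp) - ll(pm)) / (2 * eps)
                an = gs[k, i, j] if i == j else gs[k, i, j] + gs[k, j, i]
                errs.append(abs(fd - an))
                mags.append(abs(fd))
    out["sigma"] = max(errs) / max(mags)
    return out


class TestFisherScores:
    @pytest.mark.parametrize("transition_grad", ["softmax", "probability"])
    @pytest.mark.parametrize("seed", range(20))
    def test_gradients_match_finite_differences(self, seed, transition_grad):
        group = _random_hmm(2, 3, seed)
        x, _ = sample_hmm(group, 50, rng=seed + 1000)
        errs = _block_relative_errors(group, x, transition_grad)
        for block, err in errs.items():
            assert err < 1e-4, f"{block} gradient mismatch: {err}"

    def test_block_sizes_k6_m50(self):
        group = _random_hmm(6, 50, 3)
        x, _ = sample_hmm(group, 40, rng=0)
        g, bi = fisher_score(group, x)
        assert g.size == 15_342
        assert bi["sigma"].stop - bi["sigma"].start == 15_000

    def test_gaussian_gradient_vanishes_at_subject_optimum(self):
        group = _random_hmm(2, 2, 5)
        x, _ = sample_hmm(group, 2000, rng=5)
        fitted, _ = fit_group_hmm([x], K=2, n_restarts=1, random_state=5,
                                  cov_reg=0.0, tol=1e-12, max_iter=2000)
        g, bi = fisher_score(fitted, x)
        assert np.linalg.norm(g[bi["mu"]]) < 1e-3 * x.shape[0]

    def test_multisession_pi_gradient_sums_sessions(self, tiny_hmm):
        x, _ = sample_hmm(tiny_hmm, 100, rng=6, lengths=[50, 50])
        g, bi = fisher_score(tiny_hmm, x, lengths=[50, 50])
        g1, _ = fisher_score(tiny_hmm, x[:50])
        g2, _ = fisher_score(tiny_hmm, x[50:])
        assert np.allclose(g[bi["pi"]], (g1 + g2)[bi["pi"]], atol=1e-10)


class TestFisherKernel:
    def test_linear_matches_double_loop(self, tiny_hmm, sampled_series):
        fs = fisher_scores(tiny_hmm, sampled_series)
        K = fisher_kernel(fs, "linear")
        S = fs.values
        loop = np.array([[float(np.dot(S[i], S[j])) for j in range(5)] for i in range(5)])
        assert np.allclose(K, loop, rtol=1e-12)

    def test_identical_scores_gaussian_similarity_one(self, tiny_hmm, sampled_series):
        fs = fisher_scores(tiny_hmm, sampled_series)
        fs.values[1] = fs.values[0]
        K = fisher_kernel(fs, "gaussian", tau=1.0)
        assert K[0, 1] == pytest.approx(1.0)

    def test_whitened_gram_trace(self, rng):
        # N > D so the empirical Fisher information is full rank
        X = rng.standard_normal((12, 5))
        fs = FeatureSet(X, {"mu": slice(0, 5)})
        W = whiten_scores(fs)
        assert np.trace(W.values @ W.values.T) == pytest.approx(12 * 5, rel=1e-8)

    def test_whiten_requires_two_subjects(self, rng):
        fs = FeatureSet(rng.standard_normal((1, 4)), {"mu": slice(0, 4)})
        with pytest.raises(ValueError, match="2 subjects"):
            whiten_scores(fs)

    def test_block_decomposition(self, tiny_hmm, sampled_series):
        fs = fisher_scores(tiny_hmm, sampled_series)
        full = linear_kernel(fs)
        state = linear_kernel(subset_features(fs, "state_only"))
        trans = linear_kernel(subset_features(fs, "transition_only"))
        assert np.allclose(full, state + trans, rtol=1e-10)


class TestSubsets:
    def test_pca_state_width(self):
        group = _random_hmm(6, 50, 7)
        rng = np.random.default_rng(7)
        # synthetic score matrix: PCA needs more subjects than components
        X = rng.standard_normal((50, 15_342))
        _, bi = vectorise_params(group)
        fs = FeatureSet(X, bi)
        out = subset_features(fs, "pca_state", random_state=0)
        assert out.values.shape[1] == 84

    def test_transition_only_width(self):
        group = _random_hmm(6, 50, 8)
        x, _ = sample_hmm(group, 30, rng=0)
        fs = fisher_scores(group, [x, x])
        out = subset_features(fs, "transition_only")
        assert out.values.shape[1] == 42

    def test_partition_property(self, tiny_hmm, sampled_series):
        fs = fisher_scores(tiny_hmm, sampled_series)
        state = subset_features(fs, "state_only")
        trans = subset_features(fs, "transition_only")
        assert state.values.shape[1] + trans.values.shape[1] == fs.values.shape[1]

    def test_pca_rejects_too_few_subjects(self, tiny_hmm, sampled_series):
        fs = fisher_scores(tiny_hmm, sampled_series)  # 5 subjects, 6 transition cols
        with pytest.raises(ValueError, match="subjects"):
            subset_features(fs, "pca_state")


class TestKLDivergence:
    def test_self_divergence_zero(self):
        p = _random_hmm(3, 4, 9)
        assert kl_hmm(p, p) == pytest.approx(0.0, abs=1e-10)

    def test_single_state_difference_equals_weighted_gaussian_kl(self):
        p = _random_hmm(3, 4, 10)
        q = p.copy()
        q.mu[0] = q.mu[0] + 0.5
        expected = p.stationary_dist[0] * gaussian_kl(p.mu[0], p.sigma[0],
                                                      q.mu[0], q.sigma[0])
        assert kl_hmm(p, q) == pytest.approx(expected, rel=1e-10)

    def test_nonnegative_over_random_pairs(self):
        for seed in range(8):
            p = _random_hmm(2, 3, seed)
            q = _random_hmm(2, 3, seed + 100)
            assert kl_hmm(p, q) >= 0.0

    def test_mismatched_models_rejected(self):
        with pytest.raises(ValueError, match="share"):
            kl_hmm(_random_hmm(2, 3, 0), _random_hmm(3, 3, 0))

    def test_kl_kernel_properties(self):
        params = [_random_hmm(2, 3, s) for s in range(4)]
        D, K = kl_kernel(params, tau=1.0)
        assert np.allclose(np.diag(D), 0.0)
        assert np.allclose(np.diag(K), 1.0)
        assert np.allclose(D, D.T, atol=1e-10)
        assert np.all(D >= 0)
        # kernel decreases monotonically with divergence
        iu = np.triu_indices(4, k=1)
        order = np.argsort(D[iu])
        assert np.all(np.diff(K[iu][order]) <= 1e-12)


class TestSimilarityStructure:
    def test_same_generator_subjects_more_similar(self, tiny_hmm):
        perturbed = tiny_hmm.copy()
        perturbed.mu[0] = perturbed.mu[0] + 1.5
        series = [sample_hmm(tiny_hmm, 400, rng=s)[0] for s in range(4)] + \
                 [sample_hmm(perturbed, 400, rng=s + 50)[0] for s in range(4)]
        fs = fisher_scores(tiny_hmm, series)
        K = gaussian_kernel(fs, tau=1.0)
        within = np.concatenate([K[:4, :4][np.triu_indices(4, 1)],
                                 K[4:, 4:][np.triu_indices(4, 1)]])
        between = K[:4, 4:].ravel()
        assert within.mean() > between.mean()


class TestPropertyInvariants:
    """Randomised invariants, derandomised for reproducibility."""

    def test_vectorise_roundtrip_random_shapes(self):
        from hypothesis import given, settings, strategies as st

        @settings(deadline=None, derandomize=True, max_examples=25)
        @given(K=st.integers(1, 5), M=st.integers(1, 6), seed=st.integers(0, 10_000))
        def check(K, M, seed):
            p = make_base_hmm(K, M, np.random.default_rng(seed))
            vec, bi = vectorise_params(p)
            assert vec.size == K + K * K + K * M + K * M * M
            q = devectorise_params(vec, K, M)
            assert np.array_equal(q.A, p.A) and np.array_equal(q.sigma, p.sigma)

        check()

    def test_gaussian_kernels_bounded_random_inputs(self):
        from hypothesis import given, settings, strategies as st

        @settings(deadline=None, derandomize=True, max_examples=20)
        @given(n=st.integers(2, 8), d=st.integers(1, 6), seed=st.integers(0, 10_000))
        def check(n, d, seed):
            X = np.random.default_rng(seed).standard_normal((n, d))
            K = gaussian_kernel(FeatureSet(X, {"mu": slice(0, d)}), tau=1.0)
            assert np.allclose(np.diag(K), 1.0)
            assert np.all((K > 0) & (K <= 1 + 1e-12))
            assert np.allclose(K, K.T)

        check()
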