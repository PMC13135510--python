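import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from statecoupler import synthgen, tdehmm
from statecoupler.tdehmm import (
    EmbeddingConfig,
    HMMModel,
    StatePosterior,
    fit_hmm,
    fit_pca,
    forward_backward,
    fractional_occupancy,
    infer_with_canonical_states,
    match_states,
    match_states_by_sequence,
    time_delay_embed,
)


def random_model(K, P, rng):
    A = rng.dirichlet(np.ones(K), size=K)
    pi = rng.dirichlet(np.ones(K))
    covs = []
    for _ in range(K):
        M = rng.standard_normal((P, P + 2))
        covs.append(M @ M.T / (P + 2) + 0.2 * np.eye(P))
    return HMMModel(K, A, pi, np.array(covs))


def brute_force_posterior(model, Y):
    """Exhaustive path enumeration oracle for tiny instances."""
    T = Y.shape[0]
    K = model.n_states
    ll = np.array(
        [
            [
                multivariate_normal.logpdf(y, np.zeros(model.dim), model.covariances[k])
                for k in range(K)
            ]
            for y in Y
        ]
    )
    total = 0.0
    gamma = np.zeros((T, K))
    for path in itertools.product(range(K), repeat=T):
        lp = np.log(model.initial[path[0]]) + ll[0, path[0]]
        for t in range(1, T):
            lp += np.log(model.transition[path[t - 1], path[t]]) + ll[t, path[t]]
        p = np.exp(lp)
        total += p
        for t, k in enumerate(path):
            gamma[t, k] += p
    return gamma / total, np.log(total)


class TestTimeDelayEmbed:
    def test_zero_lags_is_transpose(self, rng):
        X = rng.standard_normal((2, 50))
        E, bad = time_delay_embed(X, EmbeddingConfig(0, 2))
        assert np.array_equal(E, X.T)
        assert not bad.any()

    def test_dimension_count(self, rng):
        X = rng.standard_normal((3, 100))
        E, _ = time_delay_embed(X, EmbeddingConfig(1, 3))
        assert E.shape == (98, 9)

    def test_shift_oracle(self, rng):
        x = rng.standard_normal(40)
        E, _ = time_delay_embed(x[None, :], EmbeddingConfig(2, 1))
        for t in range(E.shape[0]):
            assert np.array_equal(E[t], x[t : t + 5])  # offsets -2..+2 around t+2

    def test_column_ordering_channel_major(self, rng):
        X = rng.standard_normal((2, 30))
        E, _ = time_delay_embed(X, EmbeddingConfig(1, 2))
        # column c*(2L+1) + (l+L) = X[c, t+L+l]
        assert np.array_equal(E[:, 0], X[0, 0:28])
        assert np.array_equal(E[:, 2], X[0, 2:30])
        assert np.array_equal(E[:, 3], X[1, 0:28])

    def test_bad_sample_propagates(self, rng):
        X = rng.standard_normal((1, 30))
        bad = np.zeros(30, dtype=bool)
        bad[10] = True
        _, bad_rows = time_delay_embed(X, EmbeddingConfig(2, 1), bad_mask=bad)
        # rows touching sample 10: embedded rows 6..10 (centers 8..12)
        assert bad_rows[6:11].all()
        assert not bad_rows[:6].any() and not bad_rows[11:].any()

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError):
            time_delay_embed(rng.standard_normal((1, 5)), EmbeddingConfig(3, 1))


class TestFitPCA:
    def test_exact_subspace(self, rng):
        basis = rng.standard_normal((2, 6))
        Z = rng.standard_normal((500, 2)) @ basis
        pca = fit_pca(Z, n_components=2)
        assert pca.explained_variance_ratio().sum() == pytest.approx(1.0, abs=1e-8)

    def test_isotropic_variances_similar(self, rng):
        Z = rng.standard_normal((50_000, 5))
        pca = fit_pca(Z, n_components=5)
        ev = pca.explained_variance
        assert ev.max() / ev.min() < 1.3

    def test_reconstruction_error_nonincreasing(self, rng):
        Z = rng.standard_normal((2000, 8)) @ rng.standard_normal((8, 8))
        errs = []
        for P in range(1, 9):
            pca = fit_pca(Z, n_components=P)
            Y = pca.project(Z)
            recon = Y @ pca.components.T + pca.mean
            errs.append(np.mean((Z - recon) ** 2))
        assert all(a >= b - 1e-10 for a, b in zip(errs, errs[1:]))

    def test_orthonormal_components(self, rng):
        pca = fit_pca(rng.standard_normal((500, 6)), n_components=4)
        G = pca.components.T @ pca.components
        assert np.allclose(G, np.eye(4), atol=1e-8)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.standard_normal((100, 4)), n_components=5)


class TestForwardBackward:
    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(10):
            K = rng.integers(1, 4)
            T = rng.integers(2, 8)
            P = 2
            model = random_model(K, P, rng)
            Y = rng.standard_normal((T, P))
            post = forward_backward(model, Y)
            gamma_bf, logev_bf = brute_force_posterior(model, Y)
            assert np.abs(post.gamma - gamma_bf).max() < 1e-10
            assert abs(post.log_evidence - logev_bf) < 1e-10

    def test_symmetric_model_uniform_gamma(self, rng):
        K = 3
        cov = np.eye(2)
        model = HMMModel(
            K, np.full((K, K), 1 / K), np.full(K, 1 / K),
            np.array([cov] * K),
        )
        post = forward_backward(model, rng.standard_normal((20, 2)))
        assert np.allclose(post.gamma, 1 / K, atol=1e-12)

    def test_absorbing_state(self, rng):
        # state 2 absorbs; once entered, gamma locks onto it
        A = np.array([[0.5, 0.5], [0.0, 1.0]])
        model = HMMModel(
            2, A, np.array([0.5, 0.5]),
            np.array([np.eye(1), np.eye(1)]),
        )
        post = forward_backward(model, rng.standard_normal((30, 1)))
        g2 = post.gamma[:, 1]
        assert np.all(np.diff(g2) >= -1e-12)  # monotone commitment
        assert g2[-1] > 0.9

    def test_rows_sum_to_one(self, rng):
        model = random_model(3, 2, rng)
        post = forward_backward(model, rng.standard_normal((100, 2)))
        assert np.allclose(post.gamma.sum(axis=1), 1.0, atol=1e-10)

    def test_label_permutation_equivariance(self, rng):
        model = random_model(3, 2, rng)
        Y = rng.standard_normal((50, 2))
        post = forward_backward(model, Y)
        perm = np.array([2, 0, 1])
        post_p = forward_backward(model.permuted(perm), Y)
        assert np.allclose(post_p.gamma, post.gamma[:, perm], atol=1e-10)
        assert post_p.log_evidence == pytest.approx(post.log_evidence, abs=1e-8)

    def test_bad_rows_split_segments(self, rng):
        model = random_model(2, 2, rng)
        Y = rng.standard_normal((40, 2))
        bad = np.zeros(40, dtype=bool)
        bad[20] = True
        post = forward_backward(model, Y, bad_rows=bad)
        assert np.isnan(post.gamma[20]).all()
        # each side equals an independent run on that side
        left = forward_backward(model, Y[:20])
        assert np.allclose(post.gamma[:20], left.gamma, atol=1e-12)

    def test_matches_hmmlearn(self, rng):
        hmm = pytest.importorskip("hmmlearn.hmm")
        model = random_model(3, 2, rng)
        Y = rng.standard_normal((200, 2))
        ref = hmm.GaussianHMM(n_components=3, covariance_type="full", init_params="")
        ref.startprob_ = model.initial
        ref.transmat_ = model.transition
        ref.means_ = np.zeros((3, 2))
        ref.covars_ = model.covariances
        gamma_ref = ref.predict_proba(Y)
        post = forward_backward(model, Y)
        assert np.abs(post.gamma - gamma_ref).max() < 1e-8
        assert post.log_evidence == pytest.approx(ref.score(Y), abs=1e-8)


class TestFitHMM:
    def test_single_state_recovers_sample_covariance(self, rng):
        Y = rng.standard_normal((500, 3))
        model, post, _ = fit_hmm(Y, 1, seed=0, ridge=0.0, n_restarts=1)
        assert np.allclose(post.gamma, 1.0, atol=1e-12)
        expected = Y.T @ Y / Y.shape[0]  # zero-mean ML covariance
        assert np.allclose(model.covariances[0], expected, atol=1e-8)

    def test_loglik_monotone(self, rng):
        Y = rng.standard_normal((2000, 2)) * np.where(
            np.arange(2000)[:, None] % 200 < 100, 1.0, 2.0
        )
        _, _, hist = fit_hmm(Y, 2, seed=1, n_restarts=1, max_iter=25)
        assert np.all(np.diff(hist) > -1e-8)

    def test_two_state_recovery(self):
        rng = np.random.default_rng(99)
        spec = synthgen.MarkovSpec.uniform_sticky(2, 0.98)
        states = synthgen.sample_state_sequence(spec, 20_000, 17)
        Y = rng.standard_normal((20_000, 4)) * np.where(states == 1, 1.0, 2.0)[:, None]
        model, post, _ = fit_hmm(Y, 2, seed=0, n_restarts=2)
        perm = match_states_by_sequence(post.hard_states(), states, 2)
        acc = np.mean((perm[states - 1] + 1) == post.hard_states())
        assert acc >= 0.9
        stay = np.diag(model.transition[np.ix_(perm, perm)])
        assert np.all(np.abs(stay - 0.98) < 0.02)

    def test_k_exceeding_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_hmm(rng.standard_normal((3, 2)), 5, seed=0)


class TestCanonicalInference:
    def test_canonical_equals_generating_model(self):
        rng = np.random.default_rng(5)
        spec = synthgen.MarkovSpec.uniform_sticky(2, 0.97)
        states = synthgen.sample_state_sequence(spec, 10_000, 4)
        Y = rng.standard_normal((10_000, 3)) * np.where(states == 1, 1.0, 2.0)[:, None]
        fit_model, fit_post, _ = fit_hmm(Y, 2, seed=0, n_restarts=2)
        truth = HMMModel(
            2,
            spec.transition,
            spec.initial,
            np.array([np.eye(3), 4 * np.eye(3)]),
        )
        canon_post = infer_with_canonical_states(truth, Y)
        perm = match_states(fit_model, truth)
        assert np.abs(canon_post.gamma - fit_post.gamma[:, perm]).mean() < 0.05

    def test_single_state_gamma_ones(self, rng):
        model = HMMModel(1, np.eye(1), np.ones(1), np.array([np.eye(2)]))
        post = infer_with_canonical_states(model, rng.standard_normal((50, 2)))
        assert np.allclose(post.gamma, 1.0, atol=1e-12)

    def test_permuted_canonical_permutes_gamma(self, rng):
        model = random_model(3, 2, rng)
        Y = rng.standard_normal((100, 2))
        perm = np.array([1, 2, 0])
        a = infer_with_canonical_states(model, Y, re_estimate_transition=False)
        b = infer_with_canonical_states(
            model.permuted(perm), Y, re_estimate_transition=False
        )
        assert np.allclose(b.gamma, a.gamma[:, perm], atol=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        model = random_model(2, 3, rng)
        with pytest.raises(ValueError):
            infer_with_canonical_states(model, rng.standard_normal((50, 2)))


class TestFractionalOccupancy:
    def test_constant_gamma(self):
        gamma = np.tile([0.3, 0.7], (100, 1))
        post = StatePosterior(gamma=gamma, log_evidence=0.0)
        assert np.allclose(fractional_occupancy(post), [0.3, 0.7], atol=1e-12)

    def test_sums_to_one(self, rng):
        g = rng.dirichlet(np.ones(4), size=200)
        post = StatePosterior(gamma=g, log_evidence=0.0)
        assert fractional_occupancy(post).sum() == pytest.approx(1.0, abs=1e-10)

    def test_hard_sequence_counting(self):
        gamma = np.zeros((100, 2))
        gamma[:25, 0] = 1.0
        gamma[25:, 1] = 1.0
        post = StatePosterior(gamma=gamma, log_evidence=0.0)
        assert fractional_occupancy(post)[0] == 0.25


class TestModelSerialization:
    def test_json_roundtrip(self, tmp_path, rng):
        model = random_model(3, 4, rng)
        model.save(tmp_path / "model.json")
        back = HMMModel.load(tmp_path / "model.json")
        assert np.allclose(back.transition, model.transition)
        assert np.allclose(back.initial, model.initial)
        assert np.allclose(back.covariances, model.covariances)


class TestMatchStates:
    def test_self_match_identity(self, rng):
        model = random_model(4, 3, rng)
        assert np.array_equal(match_states(model, model), np.arange(4))

    def test_swap_recovered(self, rng):
        model = random_model(3, 3, rng)
        swapped = model.permuted(np.array([1, 0, 2]))
        perm = match_states(swapped, model)
        assert np.array_equal(perm, [1, 0, 2])

    def test_noisy_copies_recovered(self):
        base_rng = np.random.default_rng(0)
        ref = random_model(4, 3, base_rng)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            order = rng.permutation(4)
            noisy = ref.covariances[order] + 0.02 * np.array(
                [np.diag(rng.uniform(0.5, 1.5, 3)) for _ in range(4)]
            )
            est = HMMModel(4, ref.transition, ref.initial, noisy)
            perm = match_states(est, ref)
            assert np.array_equal(perm[order], np.arange(4))
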