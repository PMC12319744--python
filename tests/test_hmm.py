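"""PCA, resampling, EM fitting, Viterbi optimality, state maps, K-scan."""

import itertools

import numpy as np
import pytest

from statefuse import synth
from statefuse.hmm import (
    GaussianHMMModel,
    back_project_state_means,
    fit_gaussian_hmm,
    match_states_by_means,
    path_log_probability,
    pca_reduce,
    pca_reduce_blocks,
    resample_rate,
    scan_k,
    threshold_state_map,
    viterbi_decode,
)

# --------------------------------------------------------------------------
# oracles


def brute_force_best_path(model: GaussianHMMModel, X: np.ndarray) -> float:
    """Maximum joint log-probability over all K^T paths, by enumeration."""
    K, T = model.K, X.shape[0]
    best = -np.inf
    for path in itertools.product(range(1, K + 1), repeat=T):
        best = max(best, path_log_probability(model, X, np.array(path)))
    return best


def random_model(K: int, d: int, rng: np.random.Generator) -> GaussianHMMModel:
    P = rng.dirichlet(np.ones(K), size=K)
    pi = rng.dirichlet(np.ones(K))
    means = rng.standard_normal((K, d)) * 2
    covs = np.stack([synth._random_spd(d, rng) for _ in range(K)])
    return GaussianHMMModel(
        K=K, means=means, covariances=covs, transition=P, initial=pi,
        fit_score=0.0, n_iterations=0,
    )


# --------------------------------------------------------------------------
# PCA


class TestPCAReduce:
    def test_full_variance_round_trips(self, rng):
        X = rng.standard_normal((200, 8))
        reduced, red = pca_reduce(X, 1.0)
        assert np.max(np.abs(red.inverse_transform(reduced) - X)) <= 1e-8

    def test_rank_deficient_component_count(self, rng):
        basis = rng.standard_normal((2, 5))
        X = rng.standard_normal((300, 2)) @ basis
        _, red = pca_reduce(X, 0.9)
        assert red.n_components == 2

    def test_minimality_against_eigendecomposition(self, rng):
        X = rng.standard_normal((1000, 10)) * np.linspace(3, 0.5, 10)
        _, red = pca_reduce(X, 0.9)
        # oracle: eigenvalues of the covariance matrix
        w = np.linalg.eigvalsh(np.cov(X - X.mean(0), rowvar=False))[::-1]
        cum = np.cumsum(w) / w.sum()
        n_oracle = int(np.searchsorted(cum, 0.9 - 1e-12) + 1)
        assert red.n_components == n_oracle
        assert red.explained_fraction.sum() >= 0.9
        assert red.explained_fraction[:-1].sum() < 0.9

    def test_loadings_orthonormal(self, rng):
        _, red = pca_reduce(rng.standard_normal((500, 6)), 0.95)
        G = red.loadings.T @ red.loadings
        assert np.allclose(G, np.eye(red.n_components), atol=1e-8)

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pca_reduce(np.ones((50, 3)), 0.9)

    def test_few_timepoints_warns(self, rng):
        with pytest.warns(UserWarning, match="timepoints"):
            pca_reduce(rng.standard_normal((5, 10)), 0.9)


class TestResample:
    def test_same_rate_identity(self, rng):
        X = rng.standard_normal((100, 3))
        assert np.array_equal(resample_rate(X, 256.0, 256.0), X)

    def test_halving_length(self, rng):
        X = rng.standard_normal((512, 2))
        assert resample_rate(X, 512.0, 256.0).shape == (256, 2)

    def test_sinusoid_peak_preserved(self):
        t = np.arange(2048) / 512.0
        x = np.sin(2 * np.pi * 10.0 * t)[:, None]
        y = resample_rate(x, 512.0, 256.0)[:, 0]
        freqs = np.fft.rfftfreq(y.size, d=1 / 256.0)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(y)))]
        assert abs(peak - 10.0) <= 0.5


# --------------------------------------------------------------------------
# EM fitting


def _two_state_data(T: int, seed: int, sep: float = 8.0):
    P = np.array([[0.95, 0.05], [0.1, 0.9]])
    pi = synth.stationary_distribution(P)
    means = np.zeros((2, 3))
    means[1] = sep / np.sqrt(3)
    covs = np.stack([np.eye(3)] * 2)
    path = synth.sample_markov_chain(P, pi, T, seed)
    X = synth.emit_gaussian(path, means, covs, seed + 1)
    return X, path, P, means


class TestFitGaussianHMM:
    def test_two_state_recovery(self):
        X, path, P, means = _two_state_data(20_000, seed=2)
        model = fit_gaussian_hmm([X], K=2, n_restarts=2, seed=0)
        perm = match_states_by_means(means, model.means)
        inv = np.argsort(perm)
        decoded = inv[viterbi_decode(model, X).states - 1] + 1
        assert np.mean(decoded == path) >= 0.99
        assert np.max(np.abs(model.transition[np.ix_(perm, perm)] - P)) <= 0.03

    def test_k1_reduces_to_gaussian_mle(self, rng):
        X = rng.standard_normal((500, 4)) + 3.0
        model = fit_gaussian_hmm([X], K=1, seed=0)
        assert np.array_equal(model.transition, [[1.0]])
        assert np.allclose(model.means[0], X.mean(axis=0), atol=1e-8)

    def test_same_seed_bit_stable(self):
        X, *_ = _two_state_data(2_000, seed=5)
        a = fit_gaussian_hmm([X], K=2, n_restarts=2, seed=7)
        b = fit_gaussian_hmm([X], K=2, n_restarts=2, seed=7)
        assert a.fit_score == b.fit_score
        assert np.array_equal(a.transition, b.transition)

    def test_em_monotone_loglik(self):
        X, *_ = _two_state_data(3_000, seed=11)
        model = fit_gaussian_hmm([X], K=2, n_restarts=1, seed=1)
        diffs = np.diff(model.loglik_trace)
        assert np.all(diffs >= -1e-8 * np.abs(model.loglik_trace[:-1]))

    def test_multiple_blocks_share_model(self):
        X, *_ = _two_state_data(4_000, seed=3)
        blocks = [X[:1000], X[1000:2500], X[2500:]]
        model = fit_gaussian_hmm(blocks, K=2, n_restarts=1, seed=0)
        single = fit_gaussian_hmm([X], K=2, n_restarts=1, seed=0)
        # same emissions, nearly identical parameters despite the block cuts
        perm = match_states_by_means(single.means, model.means)
        assert np.max(np.abs(model.means[perm] - single.means)) < 0.15

    def test_transition_bias_shrinks_with_t(self):
        errs = []
        for T in (2_000, 20_000):
            X, _, P, means = _two_state_data(T, seed=13)
            model = fit_gaussian_hmm([X], K=2, n_restarts=1, seed=4)
            perm = match_states_by_means(means, model.means)
            errs.append(np.max(np.abs(model.transition[np.ix_(perm, perm)] - P)))
        assert errs[1] < errs[0]


# --------------------------------------------------------------------------
# Viterbi


class TestViterbi:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        for i in range(100):
            K = int(rng.integers(2, 4))
            T = int(rng.integers(2, 9))
            d = int(rng.integers(1, 4))
            model = random_model(K, d, rng)
            X = rng.standard_normal((T, d)) * 2
            decoded = viterbi_decode(model, X)
            lp = path_log_probability(model, X, decoded.states)
            assert lp == pytest.approx(brute_force_best_path(model, X), abs=1e-9)

    def test_emissions_at_state_mean_give_constant_path(self):
        means = np.array([[0.0, 0.0], [50.0, 50.0]])
        covs = np.stack([np.eye(2)] * 2)
        model = GaussianHMMModel(
            K=2, means=means, covariances=covs,
            transition=np.array([[0.99, 0.01], [0.01, 0.99]]),
            initial=np.array([0.5, 0.5]), fit_score=0.0, n_iterations=0,
        )
        X = np.zeros((6, 2))
        assert viterbi_decode(model, X).states.tolist() == [1] * 6

    def test_tie_breaks_to_lowest_state_index(self):
        # indistinguishable states: every path has equal probability
        means = np.zeros((2, 1))
        covs = np.stack([np.eye(1)] * 2)
        model = GaussianHMMModel(
            K=2, means=means, covariances=covs,
            transition=np.full((2, 2), 0.5), initial=np.array([0.5, 0.5]),
            fit_score=0.0, n_iterations=0,
        )
        X = np.zeros((5, 1))
        assert viterbi_decode(model, X).states.tolist() == [1] * 5

    def test_label_permutation_equivariance(self, rng):
        model = random_model(3, 2, rng)
        X = rng.standard_normal((40, 2))
        base = viterbi_decode(model, X).states
        perm = np.array([2, 0, 1])  # new state i = old state perm[i]
        permuted = viterbi_decode(model.permute_states(perm), X).states
        inv = np.argsort(perm)
        assert np.array_equal(permuted, inv[base - 1] + 1)


class TestAgainstHmmlearn:
    """Independent cross-checks against an external HMM implementation."""

    def _hmmlearn_model(self, model):
        from hmmlearn.hmm import GaussianHMM

        h = GaussianHMM(n_components=model.K, covariance_type="full", init_params="")
        h.startprob_ = model.initial
        h.transmat_ = model.transition
        h.means_ = model.means
        h.covars_ = model.covariances
        return h

    def test_loglikelihood_agrees(self, rng):
        from statefuse.hmm import _e_step

        model = random_model(3, 2, rng)
        X = rng.standard_normal((200, 2))
        ll, *_ = _e_step(
            [X], model.means, model.covariances, model.transition, model.initial
        )
        assert ll == pytest.approx(self._hmmlearn_model(model).score(X), abs=1e-6)

    def test_viterbi_agrees_on_separated_data(self, rng):
        X, path, P, means = _two_state_data(1_000, seed=17)
        model = fit_gaussian_hmm([X], K=2, n_restarts=1, seed=0)
        ours = viterbi_decode(model, X).states - 1
        _, theirs = self._hmmlearn_model(model).decode(X, algorithm="viterbi")
        assert np.mean(ours == theirs) >= 0.999


# --------------------------------------------------------------------------
# state maps


class TestStateMaps:
    def test_identity_loadings_give_means(self, rng):
        model = random_model(3, 4, rng)
        from statefuse.hmm import PCAReduction

        model.reduction = PCAReduction(
            loadings=np.eye(4), channel_means=np.zeros(4),
            explained_fraction=np.full(4, 0.25), n_components=4,
        )
        assert np.allclose(back_project_state_means(model), model.means.T)

    def test_unit_mean_selects_loading_column(self, rng):
        from statefuse.hmm import PCAReduction

        loadings, _ = np.linalg.qr(rng.standard_normal((6, 3)))
        model = random_model(2, 3, rng)
        model.means = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        model.reduction = PCAReduction(
            loadings=loadings, channel_means=np.zeros(6),
            explained_fraction=np.full(3, 0.3), n_components=3,
        )
        M = back_project_state_means(model)
        assert np.allclose(M[:, 0], loadings[:, 0])

    def test_matches_direct_product(self, rng):
        from statefuse.hmm import PCAReduction

        loadings, _ = np.linalg.qr(rng.standard_normal((8, 3)))
        model = random_model(4, 3, rng)
        model.reduction = PCAReduction(
            loadings=loadings, channel_means=rng.standard_normal(8),
            explained_fraction=np.full(3, 0.3), n_components=3,
        )
        assert np.allclose(back_project_state_means(model), loadings @ model.means.T)

    def test_missing_reduction_raises(self, rng):
        with pytest.raises(ValueError, match="reduction"):
            back_project_state_means(random_model(2, 2, rng))

    def test_reduced_fit_back_projection_consistency(self, rng):
        # with all variance retained, back-projected means equal channel-space
        # state means up to the removed channel mean
        X, path, P, means_true = _two_state_data(4_000, seed=19)
        reduced, red = pca_reduce_blocks([X], 1.0)
        model = fit_gaussian_hmm(reduced, K=2, n_restarts=1, seed=0, reduction=red)
        M = back_project_state_means(model)  # channels x K
        decoded = viterbi_decode(model, reduced[0]).states
        for k in range(2):
            emp = X[decoded == k + 1].mean(axis=0) - red.channel_means
            assert np.allclose(M[:, k], emp, atol=0.05)


class TestThresholdStateMap:
    def test_order_statistics_count(self):
        col = np.array([1, -2, 3, -4, 5, -6, 7, -8, 9, 10], dtype=float)
        out = threshold_state_map(col[:, None], 70.0)
        survivors = out[out != 0]
        assert sorted(np.abs(survivors)) == [8, 9, 10]

    def test_zero_percentile_keeps_everything(self, rng):
        M = rng.standard_normal((20, 3))
        out = threshold_state_map(M, 0.0)
        assert np.array_equal(out, M)

    def test_all_equal_column_survives(self):
        M = np.full((10, 1), 2.5)
        assert np.array_equal(threshold_state_map(M, 70.0), M)


# --------------------------------------------------------------------------
# K selection


class TestScanK:
    def test_true_k_clean_excess_k_flagged(self):
        flags_true, flags_over = [], []
        for seed in range(5):
            P = np.array([[0.9, 0.05, 0.05], [0.05, 0.9, 0.05], [0.05, 0.05, 0.9]])
            pi = synth.stationary_distribution(P)
            path = synth.sample_markov_chain(P, pi, 1_500, seed)
            means = np.array([[0.0, 0.0], [8.0, 0.0], [0.0, 8.0]])
            covs = np.stack([np.eye(2)] * 3)
            X = synth.emit_gaussian(path, means, covs, seed + 100)
            report = scan_k([X], [3, 8], seed=seed, n_restarts=1)
            e3, e8 = report.entries
            flags_true.append(int(e3.under_represented.sum() + e3.over_represented.sum()))
            flags_over.append(int(e8.under_represented.sum()))
        assert sum(f == 0 for f in flags_true) >= 3
        assert sum(f >= 1 for f in flags_over) >= 3

    def test_uniform_transition_inflow(self, rng):
        from statefuse.hmm import KSelectionEntry, KSelectionReport

        # in-flow score of a uniform matrix is exactly 1/K, below the ceiling
        K = 4
        uniform = np.full((K, K), 1.0 / K)
        off = uniform.copy()
        np.fill_diagonal(off, np.nan)
        inflow = np.nanmean(off, axis=0)
        assert np.allclose(inflow, 1.0 / K)
        assert not np.any(inflow > 2.0 / K)

    def test_never_visited_state_flagged(self):
        # FO = 0 < 0.5/K regardless of K
        fo = np.array([0.5, 0.5, 0.0])
        assert (fo < 0.5 / 3)[2]
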