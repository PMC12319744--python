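"""Generator behaviour: chain sampling, emissions, planted effects, tracks."""

import numpy as np
import pandas as pd
import pytest

from statefuse import synth
from statefuse.synth import (
    ConditionEffect,
    MouseCoupling,
    SynthStudyConfig,
    emit_gaussian,
    generate_brain_study,
    generate_mouse_tracks,
    generate_music_features,
    sample_markov_chain,
    stationary_distribution,
)


class TestSampleMarkovChain:
    def test_deterministic_alternation(self):
        path = sample_markov_chain([[0, 1], [1, 0]], [1, 0], 4, seed=0)
        assert path.tolist() == [1, 2, 1, 2]

    def test_absorbing_states(self):
        path = sample_markov_chain(np.eye(3), [0, 0, 1], 5, seed=0)
        assert path.tolist() == [3, 3, 3, 3, 3]

    def test_empirical_transition_frequencies_converge(self):
        # law of large numbers: transition counts approach the matrix
        P = np.array([[0.9, 0.1], [0.2, 0.8]])
        path = sample_markov_chain(P, stationary_distribution(P), 100_000, seed=7)
        counts = np.zeros((2, 2))
        np.add.at(counts, (path[:-1] - 1, path[1:] - 1), 1.0)
        emp = counts / counts.sum(axis=1, keepdims=True)
        assert np.max(np.abs(emp - P)) <= 0.01

    def test_non_stochastic_row_rejected(self):
        with pytest.raises(ValueError, match="row 2"):
            sample_markov_chain([[0.5, 0.5], [0.5, 0.6]], [1, 0], 3, seed=0)

    def test_reproducible(self):
        P = [[0.7, 0.3], [0.4, 0.6]]
        a = sample_markov_chain(P, [0.5, 0.5], 500, seed=11)
        b = sample_markov_chain(P, [0.5, 0.5], 500, seed=11)
        assert np.array_equal(a, b)


class TestEmitGaussian:
    def test_zero_covariance_reproduces_means(self):
        means = np.array([[1.0, 2.0], [-3.0, 4.0]])
        out = emit_gaussian([2, 1, 2], means, np.zeros((2, 2, 2)), seed=0)
        assert np.array_equal(out, means[[1, 0, 1]])

    def test_sample_mean_standard_error_bound(self):
        # single state, isotropic unit variance: mean within 3 SE
        n, d = 50_000, 5
        mu = np.array([[2.0, -1.0, 0.5, 0.0, 3.0]])
        covs = np.eye(d)[None]
        X = emit_gaussian(np.ones(n, dtype=int), mu, covs, seed=3)
        assert np.all(np.abs(X.mean(axis=0) - mu[0]) < 3.0 / np.sqrt(n))

    def test_output_shape(self):
        K, d = 3, 68
        means = np.zeros((K, d))
        covs = np.stack([np.eye(d)] * K)
        out = emit_gaussian(np.array([1, 2, 3, 1, 2, 3, 1]), means, covs, seed=0)
        assert out.shape == (7, d)

    def test_invalid_covariance_rejected(self):
        bad = np.stack([np.eye(2), -np.eye(2)])
        with pytest.raises(ValueError, match="positive definite"):
            emit_gaussian([1, 2], np.zeros((2, 2)), bad, seed=0)


def _small_config(**over):
    base = dict(
        n_participants=3,
        n_excerpts_control=2,
        n_excerpts_experiment=2,
        n_rest_blocks=1,
        n_channels=4,
        sample_rate=256.0,
        block_duration=40.0,
        K_true=3,
        seed=5,
    )
    base.update(over)
    return SynthStudyConfig(**base)


class TestGenerateBrainStudy:
    def test_block_count(self):
        study, _ = generate_brain_study(
            _small_config(sample_rate=16.0, block_duration=2.0)
        )
        assert len(study) == 3 * (2 + 2 + 1)

    def test_no_effect_shares_one_model(self):
        study, truth = generate_brain_study(
            _small_config(sample_rate=16.0, block_duration=2.0)
        )
        assert truth.condition_effect == "none"
        assert truth.effect_transition is None

    def test_planted_fo_effect_visible_in_true_paths(self):
        # +0.15 occupancy of state 2 in experiment blocks, 10240 samples each
        cfg = _small_config()
        assert cfg.block_length == 10_240
        effect = ConditionEffect(state=2, delta_fo=0.15, condition="experiment")
        study, truth = generate_brain_study(cfg, effect)
        fo_exp = synth.empirical_fo_from_paths(truth, study, "experiment")
        fo_ctl = synth.empirical_fo_from_paths(truth, study, "control")
        assert fo_exp[1] - fo_ctl[1] == pytest.approx(0.15, abs=0.03)

    def test_invalid_effect_magnitude_rejected(self):
        cfg = _small_config(sample_rate=16.0, block_duration=2.0)
        effect = ConditionEffect(state=1, delta_fo=0.95)
        with pytest.raises(ValueError):
            generate_brain_study(cfg, effect)

    def test_reproducibility_bit_identical(self):
        cfg = _small_config(sample_rate=16.0, block_duration=2.0)
        s1, t1 = generate_brain_study(cfg)
        s2, t2 = generate_brain_study(cfg)
        assert np.array_equal(s1[0].data, s2[0].data)
        assert all(
            np.array_equal(t1.true_paths[k], t2.true_paths[k]) for k in t1.true_paths
        )

    def test_ground_truth_invariants(self):
        _, truth = generate_brain_study(_small_config(sample_rate=16.0, block_duration=2.0))
        assert np.allclose(truth.true_transition.sum(axis=1), 1.0, atol=1e-12)
        for S in truth.true_covs:
            assert np.allclose(S, S.T)
            assert np.linalg.eigvalsh(S).min() > 0
        assert all(np.isfinite(b.data).all() for b in generate_brain_study(
            _small_config(sample_rate=16.0, block_duration=2.0))[0])


class TestGenerateMusicFeatures:
    def test_shape_and_columns(self):
        ms = generate_music_features(2, durations=40.0, seed=0)
        assert ms.features[0].shape == (400, 18)
        assert list(ms.features[0].columns) == list(synth.MIR_FEATURES)

    def test_zero_noise_rows_equal_regime_means(self):
        ms = generate_music_features(1, durations=10.0, seed=2, noise_scale=0.0)
        X = ms.features[0].to_numpy()
        path = ms.true_paths[0]
        assert np.array_equal(X, ms.means[path - 1])
        # nearest-mean decoding recovers the paths exactly
        d2 = ((X[:, None, :] - ms.means[None]) ** 2).sum(axis=2)
        assert np.array_equal(d2.argmin(axis=1) + 1, path)

    def test_non_integral_duration_rounds_down(self):
        ms = generate_music_features(1, durations=4.55, seed=0)
        assert ms.features[0].shape[0] == 45


class TestGenerateMouseTracks:
    def test_tracks_start_at_origin(self):
        study, _ = generate_brain_study(_small_config(sample_rate=16.0, block_duration=2.0))
        tracks = generate_mouse_tracks(study, seed=0)
        assert len(tracks) == 3 * 4  # excerpt blocks only
        for df in tracks.values():
            assert df.loc[0, "x"] == 0.0 and df.loc[0, "y"] == 0.0

    def test_zero_step_no_coupling_stays_at_origin(self):
        study, _ = generate_brain_study(_small_config(sample_rate=16.0, block_duration=2.0))
        tracks = generate_mouse_tracks(study, seed=0, step=0.0)
        for df in tracks.values():
            assert np.all(df[["x", "y"]].to_numpy() == 0.0)

    def test_coupled_subgroup_dwells_in_target_quadrant(self):
        study, _ = generate_brain_study(
            _small_config(sample_rate=16.0, block_duration=8.0)
        )
        coupled = ["sub01"]
        tracks = generate_mouse_tracks(
            study,
            MouseCoupling(target_quadrant=3, participants=coupled, drift=2.0),
            seed=4,
        )
        def q3_fo(df):
            xy = df[["x", "y"]].to_numpy()
            return np.mean((xy[:, 0] < 0) & (xy[:, 1] < 0))
        fo_coupled = np.mean([q3_fo(df) for (p, _), df in tracks.items() if p in coupled])
        fo_rest = np.mean([q3_fo(df) for (p, _), df in tracks.items() if p not in coupled])
        assert fo_coupled - fo_rest > 0.2


class TestConditionEffectMachinery:
    def test_boost_solves_exact_stationary_shift(self):
        P = np.array([[0.8, 0.1, 0.1], [0.15, 0.7, 0.15], [0.25, 0.25, 0.5]])
        b = synth.solve_fo_boost(P, 2, 0.2)
        P2 = synth.boost_self_transition(P, 2, b)
        pi, pi2 = stationary_distribution(P), stationary_distribution(P2)
        assert pi2[1] - pi[1] == pytest.approx(0.2, abs=1e-9)
        assert np.allclose(P2.sum(axis=1), 1.0)

    def test_out_of_range_boost_rejected(self):
        P = np.array([[0.9, 0.1], [0.1, 0.9]])
        with pytest.raises(ValueError):
            synth.boost_self_transition(P, 1, 0.5)
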