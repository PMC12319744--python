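"""PLS decompositions: closed forms, oracles, permutation and bootstrap."""

import numpy as np
import pytest

from statefuse.pls import (
    MAX_BOOTSTRAP_RATIO,
    behavioral_pls,
    mean_centered_pls,
    procrustes_align,
)


def _cosine(a, b):
    return np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))


class TestMeanCenteredClosedForms:
    def test_two_conditions_rank_one(self, rng):
        # exactly one nonzero singular value; contrast +-1/sqrt(2); variable
        # salience parallel to the condition mean difference
        m1 = np.array([1.0, -2.0, 0.5, 3.0])
        m2 = np.array([0.0, 1.0, 1.5, -1.0])
        X = np.vstack([m1 + 0 * rng.standard_normal(4) for _ in range(10)]
                      + [m2 for _ in range(10)])
        labels = ["a"] * 10 + ["b"] * 10
        res = mean_centered_pls(X, labels, n_perm=0, n_boot=0)
        assert res.singular_values[0] > 1e-8
        assert np.all(res.singular_values[1:] < 1e-10)
        assert abs(abs(res.design_saliences[0, 0]) - 1 / np.sqrt(2)) < 1e-10
        assert abs(_cosine(res.variable_saliences[:, 0], m1 - m2)) >= 1 - 1e-10

    def test_identical_condition_means_all_zero(self):
        X = np.tile(np.array([1.0, 2.0, 3.0]), (8, 1))
        res = mean_centered_pls(X, ["a"] * 4 + ["b"] * 4, n_perm=50, n_boot=0, seed=0)
        assert np.all(res.singular_values < 1e-12)
        assert res.perm_p[0] == 1.0

    def test_three_conditions_recover_offset_subspace(self, rng):
        # planted orthogonal condition offsets span the LV subspace
        p = 6
        e1 = np.eye(p)[0]
        e2 = np.eye(p)[1]
        offsets = {"a": 3 * e1, "b": 3 * e2, "c": np.zeros(p)}
        X, labels = [], []
        for c, off in offsets.items():
            for _ in range(5):
                X.append(off + 1e-9 * rng.standard_normal(p))
                labels.append(c)
        res = mean_centered_pls(np.array(X), labels, n_perm=0, n_boot=0)
        V = res.variable_saliences[:, :2]
        # oracle subspace via eigendecomposition of the deviation Gram matrix
        span = np.stack([e1, e2]).T
        proj = span @ np.linalg.lstsq(span, V, rcond=None)[0]
        angles = np.linalg.norm(V - proj, axis=0)
        assert np.all(angles < 1e-6)

    def test_svd_reconstruction_and_energy(self, rng):
        X = rng.standard_normal((30, 5))
        labels = (["a", "b", "c"] * 10)[:30]
        res = mean_centered_pls(X, labels, n_perm=0, n_boot=0)
        M = np.stack([X[np.array(labels) == c].mean(0) for c in res.condition_order])
        D = M - M.mean(0)
        recon = res.design_saliences @ np.diag(res.singular_values) @ res.variable_saliences.T
        assert np.max(np.abs(recon - D)) <= 1e-8
        assert np.sum(res.singular_values**2) == pytest.approx(np.sum(D**2), abs=1e-8)
        for S in (res.design_saliences, res.variable_saliences):
            assert np.allclose(S.T @ S, np.eye(S.shape[1]), atol=1e-8)


class TestBehavioralClosedForms:
    def test_single_identical_column_gives_unit_singular_value(self, rng):
        x = rng.standard_normal((12, 1))
        res = behavioral_pls(x, x.copy(), n_perm=0, n_boot=0)
        assert res.singular_values[0] == pytest.approx(1.0)

    def test_singular_values_match_eigendecomposition(self, rng):
        X = rng.standard_normal((20, 4))
        Y = rng.standard_normal((20, 3))
        res = behavioral_pls(X, Y, n_perm=0, n_boot=0)
        # oracle: sqrt of eigenvalues of R^T R on the same correlation stack
        Xz = (X - X.mean(0)) / X.std(0)
        Yz = (Y - Y.mean(0)) / Y.std(0)
        R = Yz.T @ Xz / 20
        w = np.sqrt(np.maximum(np.linalg.eigvalsh(R.T @ R), 0))[::-1]
        assert np.allclose(np.sort(res.singular_values)[::-1], w[: res.n_lv], atol=1e-10)

    def test_column_scaling_invariance(self, rng):
        X = rng.standard_normal((15, 3))
        Y = rng.standard_normal((15, 2))
        res1 = behavioral_pls(X, Y, n_perm=40, n_boot=0, seed=3)
        res2 = behavioral_pls(X * np.array([10.0, 0.01, 5.0]), Y, n_perm=40, n_boot=0, seed=3)
        assert np.allclose(res1.singular_values, res2.singular_values, atol=1e-10)
        assert np.allclose(res1.perm_p, res2.perm_p)


class TestPermutation:
    def test_minimum_p_when_observed_dominates(self, rng):
        # strong planted effect: observed singular value beats all permutations
        n = 16
        labels = ["a"] * n + ["b"] * n
        shift = np.array([8.0, -8.0, 8.0])
        X = np.vstack(
            [rng.standard_normal(3) * 0.1 for _ in range(n)]
            + [shift + rng.standard_normal(3) * 0.1 for _ in range(n)]
        )
        res = mean_centered_pls(X, labels, n_perm=99, n_boot=0, seed=0)
        assert res.perm_p[0] == pytest.approx(1.0 / 100.0)

    def test_power_with_two_sd_shift(self):
        # mean shift of 2 SD, n = 17 per condition: p <= 0.01 almost always
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = np.vstack(
                [rng.standard_normal(5) for _ in range(17)]
                + [rng.standard_normal(5) + 2.0 for _ in range(17)]
            )
            res = mean_centered_pls(
                X, ["a"] * 17 + ["b"] * 17, n_perm=500, n_boot=0, seed=seed
            )
            hits += int(res.perm_p[0] <= 0.01)
        assert hits >= 9

    def test_p_bounds(self, rng):
        X = rng.standard_normal((20, 4))
        res = mean_centered_pls(X, ["a", "b"] * 10, n_perm=100, n_boot=0, seed=1)
        assert np.all(res.perm_p >= 1 / 101) and np.all(res.perm_p <= 1.0)


class TestProcrustes:
    def test_sign_flip_restored(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((6, 3)))
        flipped = Q * np.array([-1, 1, -1])
        assert np.allclose(procrustes_align(Q, flipped), Q, atol=1e-10)

    def test_order_swap_restored(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((6, 3)))
        swapped = Q[:, [1, 0, 2]]
        assert np.allclose(procrustes_align(Q, swapped), Q, atol=1e-10)

    def test_random_rotation_inverted(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((8, 4)))
        R, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        assert np.linalg.norm(procrustes_align(Q, Q @ R) - Q) <= 1e-8


class TestBootstrap:
    def test_noise_free_ratios_capped(self):
        # deterministic rank-1 structure: zero bootstrap SE, capped ratios
        v = np.array([1.0, -1.0, 0.5])
        X = np.vstack([np.tile(v, (6, 1)), np.tile(-v, (6, 1))])
        labels = ["a"] * 6 + ["b"] * 6
        res = mean_centered_pls(X, labels, n_perm=0, n_boot=30, seed=0)
        big = np.abs(res.variable_saliences[:, 0]) > 1e-12
        assert np.all(np.abs(res.bootstrap_ratios[big, 0]) == MAX_BOOTSTRAP_RATIO)

    def test_reliable_variable_has_large_ratio(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 17
            effect = np.zeros(6)
            effect[0] = 4.0  # one heavily salient variable
            X = np.vstack(
                [rng.standard_normal(6) for _ in range(n)]
                + [effect + rng.standard_normal(6) for _ in range(n)]
            )
            res = mean_centered_pls(
                X, ["a"] * n + ["b"] * n, n_perm=0, n_boot=100, seed=seed
            )
            hits += int(np.abs(res.bootstrap_ratios[0, 0]) > 2.58)
        assert hits >= 9

    def test_ci_bounds_bracket_point_estimate(self, rng):
        X = rng.standard_normal((24, 5))
        labels = ["a", "b", "c"] * 8
        res = mean_centered_pls(X, labels, n_perm=0, n_boot=50, seed=2)
        assert np.all(res.ci_low <= res.design_saliences + 1e-12)
        assert np.all(res.design_saliences <= res.ci_high + 1e-12)

    def test_participant_rows_move_together(self, rng):
        # resampling must preserve the row pairing across conditions: with
        # a perfect X/Y participant-level dependency the correlation
        # structure survives every resample
        n = 10
        u = rng.standard_normal(n)
        X = np.concatenate([u, u * 2])[:, None]
        Y = np.concatenate([u, u * 2])[:, None] * 3.0
        labels = ["a"] * n + ["b"] * n
        parts = [f"p{i}" for i in range(n)] * 2
        res = behavioral_pls(
            X, Y, labels, n_perm=0, n_boot=40, seed=1, participants=parts
        )
        assert np.abs(res.bootstrap_ratios[0, 0]) == MAX_BOOTSTRAP_RATIO
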