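"""Solution stability across repeated HMM fits: RV similarity and STATIS.

EM from random restarts can land in different local optima, so a state
decomposition is only trustworthy if repeated fits agree.  Agreement is
measured on the per-state covariance matrices ("state matrices"): runs are
matched state-to-state (labels are arbitrary), each run's matched
covariances are assembled into one block-diagonal symmetric matrix, and
runs are compared pairwise with the RV coefficient — a matrix correlation
in [0, 1] for positive semi-definite inputs.  STATIS turns the pairwise RV
similarity matrix into per-run weights (its leading eigenvector, positive
by Perron–Frobenius, rescaled to sum one) and a weighted consensus
("compromise") matrix; an outlying run receives the smallest weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .hmm import GaussianHMMModel, fit_gaussian_hmm


def rv_coefficient(S1: np.ndarray, S2: np.ndarray) -> float:
    """RV = tr(S1 S2) / sqrt(tr(S1^2) tr(S2^2)); NaN for a zero matrix."""
    A = np.asarray(S1, dtype=float)
    B = np.asarray(S2, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("inputs must be square matrices of equal size")
    na = float(np.sum(A * A))
    nb = float(np.sum(B * B))
    if na == 0.0 or nb == 0.0:
        return float("nan")
    return float(np.sum(A * B) / np.sqrt(na * nb))


def statis(matrices: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Per-run weights and the weighted consensus of symmetric PSD matrices.

    Weights are the leading eigenvector of the pairwise RV matrix, made
    non-negative and rescaled to sum one; the compromise is the
    weight-averaged matrix (PSD as a convex combination of PSD inputs).
    """
    if len(matrices) < 2:
        raise ValueError("STATIS needs >= 2 matrices")
    n = len(matrices)
    R = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            R[i, j] = R[j, i] = rv_coefficient(matrices[i], matrices[j])
    if np.any(np.isnan(R)):
        raise ValueError("a zero matrix makes the RV similarity undefined")
    vals, vecs = np.linalg.eigh(R)
    w = vecs[:, -1]
    w = np.abs(w)  # Perron vector of a non-negative matrix, sign-fixed
    w = w / w.sum()
    compromise = np.zeros_like(np.asarray(matrices[0], dtype=float))
    for wi, S in zip(w, matrices):
        compromise += wi * np.asarray(S, dtype=float)
    return w, compromise


def match_states_by_rv(
    ref_covs: np.ndarray, covs: np.ndarray, greedy: bool = True
) -> np.ndarray:
    """Permutation aligning a run's states to a reference run's states.

    Similarity is the pairwise RV of state covariances.  The default greedy
    pass repeatedly takes the best remaining (reference, run) pair;
    ``greedy=False`` solves the assignment optimally (Hungarian).
    Returns ``perm`` with run state ``perm[i]`` matched to reference state
    ``i`` (0-based).
    """
    K = ref_covs.shape[0]
    sim = np.array(
        [[rv_coefficient(ref_covs[i], covs[j]) for j in range(K)] for i in range(K)]
    )
    if not greedy:
        _, cols = linear_sum_assignment(-sim)
        return cols
    perm = np.full(K, -1)
    used_i = np.zeros(K, bool)
    used_j = np.zeros(K, bool)
    work = sim.copy()
    for _ in range(K):
        work[used_i, :] = -np.inf
        work[:, used_j] = -np.inf
        i, j = np.unravel_index(np.argmax(work), work.shape)
        perm[i] = j
        used_i[i] = True
        used_j[j] = True
    return perm


@dataclass
class StabilityReport:
    """Dispersion and similarity of repeated fits."""

    fit_scores: np.ndarray  # per-run per-sample negative log-likelihood
    rv_matrix: np.ndarray  # runs x runs, unit diagonal
    statis_weights: np.ndarray  # non-negative, sums to one
    compromise: np.ndarray  # consensus block-diagonal state-covariance matrix
    models: list[GaussianHMMModel]
    failed_runs: list[int]

    @property
    def fit_score_mean(self) -> float:
        return float(np.mean(self.fit_scores))

    @property
    def fit_score_sd(self) -> float:
        return float(np.std(self.fit_scores, ddof=1)) if self.fit_scores.size > 1 else 0.0

    @property
    def relative_dispersion(self) -> float:
        return self.fit_score_sd / abs(self.fit_score_mean)


def _state_block_matrix(covs: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Block-diagonal stack of matched state covariances: (K d) x (K d)."""
    K, d, _ = covs.shape
    out = np.zeros((K * d, K * d))
    for i, j in enumerate(perm):
        out[i * d : (i + 1) * d, i * d : (i + 1) * d] = covs[j]
    return out


def stability_suite(
    blocks,
    K: int,
    n_runs: int = 50,
    seed: int | None = None,
    n_restarts: int = 1,
    greedy: bool = True,
    **fit_kwargs,
) -> StabilityReport:
    """Fit ``n_runs`` models from distinct seeds and compare their states.

    Runs that fail outright are excluded and reported.  States of each run
    are matched to the first successful run by RV of their covariances
    before the runs are compared.
    """
    if n_runs < 2:
        raise ValueError("stability assessment needs >= 2 runs")
    master = np.random.default_rng(seed)
    run_seeds = master.integers(2**31 - 1, size=n_runs)
    models: list[GaussianHMMModel] = []
    failed: list[int] = []
    for r in range(n_runs):
        try:
            models.append(
                fit_gaussian_hmm(
                    blocks, K=K, n_restarts=n_restarts, seed=int(run_seeds[r]), **fit_kwargs
                )
            )
        except Exception:  # a diverged run must not sink the suite
            failed.append(r)
    if len(models) < 2:
        raise RuntimeError("fewer than two runs succeeded; stability undefined")
    ref = models[0].covariances
    stacks = []
    for m in models:
        perm = match_states_by_rv(ref, m.covariances, greedy=greedy)
        stacks.append(_state_block_matrix(m.covariances, perm))
    n = len(stacks)
    R = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            R[i, j] = R[j, i] = rv_coefficient(stacks[i], stacks[j])
    weights, compromise = statis(stacks)
    return StabilityReport(
        fit_scores=np.array([m.fit_score for m in models]),
        rv_matrix=R,
        statis_weights=weights,
        compromise=compromise,
        models=models,
        failed_runs=failed,
    )
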