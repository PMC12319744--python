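"""Gaussian hidden Markov modelling of PCA-reduced multichannel time series.

The estimation pipeline mirrors common practice for electrophysiological
state decoding: channels are reduced by PCA to the smallest subspace
holding a requested fraction of variance (default 90%), optionally
resampled to a common rate, and a K-state Gaussian HMM with full
covariances is fitted by maximum-likelihood EM (Baum–Welch) with multiple
restarts.  State paths are decoded with the Viterbi algorithm, and state
means are projected back through the PCA loadings for channel-space
interpretation.

Blocks are treated as independent sequences sharing one model: the forward
recursion restarts from the model's initial distribution at every block
boundary, so no spurious transitions are counted across task boundaries.

Numerical scheme: emission densities are evaluated in the log domain;
forward–backward uses the classic per-step scaled recursions (each step
normalised to sum one, with the per-step log scale factors accumulated
into the log-likelihood), which is algebraically equivalent to a log-domain
implementation and allows batching many equal-length blocks into single
matrix operations.  Viterbi runs fully in the log domain with a
lowest-state-index tie-break.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import h5py
import numpy as np
from scipy import signal
from scipy.linalg import solve_triangular
from sklearn.cluster import KMeans

from .datasets import StudyDataset

# --------------------------------------------------------------------------
# PCA reduction


@dataclass
class PCAReduction:
    """Orthonormal channel-space basis retaining a variance fraction."""

    loadings: np.ndarray  # channels x components, orthonormal columns
    channel_means: np.ndarray  # channels
    explained_fraction: np.ndarray  # per retained component
    n_components: int

    def transform(self, data: np.ndarray) -> np.ndarray:
        return (np.asarray(data, dtype=float) - self.channel_means) @ self.loadings

    def inverse_transform(self, reduced: np.ndarray) -> np.ndarray:
        return reduced @ self.loadings.T + self.channel_means


def pca_reduce(
    data: np.ndarray, variance_fraction: float = 0.9
) -> tuple[np.ndarray, PCAReduction]:
    """Project centred data onto the minimal PCA subspace holding the fraction.

    The retained component count is minimal: dropping the last retained
    component would push the cumulative explained variance below the
    requested fraction.  ``variance_fraction=1.0`` retains the full rank of
    the data, so reconstruction is exact to rounding.
    """
    if not 0.0 < variance_fraction <= 1.0:
        raise ValueError("variance_fraction must be in (0, 1]")
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be timepoints x channels")
    T, d = X.shape
    if T <= d:
        warnings.warn(
            f"only {T} timepoints for {d} channels; PCA may be unstable",
            stacklevel=2,
        )
    mu = X.mean(axis=0)
    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        raise ValueError("data has zero variance; PCA is undefined")
    frac = var / total
    cum = np.cumsum(frac)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if variance_fraction >= 1.0:
        n = rank
    else:
        n = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
        n = min(n, rank)
    loadings = Vt[:n].T
    reduction = PCAReduction(
        loadings=loadings,
        channel_means=mu,
        explained_fraction=frac[:n],
        n_components=n,
    )
    return Xc @ loadings, reduction


def pca_reduce_blocks(
    blocks: list[np.ndarray], variance_fraction: float = 0.9
) -> tuple[list[np.ndarray], PCAReduction]:
    """Fit one PCA basis on the concatenation of all blocks, then split back."""
    lengths = [b.shape[0] for b in blocks]
    stacked = np.vstack(blocks)
    reduced, reduction = pca_reduce(stacked, variance_fraction)
    out, i = [], 0
    for L in lengths:
        out.append(reduced[i : i + L])
        i += L
    return out, reduction


# --------------------------------------------------------------------------
# resampling


def resample_rate(data: np.ndarray, from_hz: float, to_hz: float) -> np.ndarray:
    """Polyphase resampling with anti-aliasing; output length round(T*to/from)."""
    if from_hz <= 0 or to_hz <= 0:
        raise ValueError("rates must be positive")
    X = np.asarray(data, dtype=float)
    if from_hz == to_hz:
        return X.copy()
    ratio = Fraction(to_hz / from_hz).limit_denominator(10_000)
    out = signal.resample_poly(X, ratio.numerator, ratio.denominator, axis=0)
    target = int(round(X.shape[0] * to_hz / from_hz))
    return out[:target]


# --------------------------------------------------------------------------
# model container


@dataclass
class GaussianHMMModel:
    """A fitted K-state Gaussian HMM in reduced space."""

    K: int
    means: np.ndarray  # K x n_components
    covariances: np.ndarray  # K x n_components x n_components
    transition: np.ndarray  # K x K row-stochastic
    initial: np.ndarray  # K
    fit_score: float  # per-sample negative log-likelihood
    n_iterations: int
    seed: int | None = None
    reduction: PCAReduction | None = None
    converged: bool = True
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_components(self) -> int:
        return self.means.shape[1]

    def permute_states(self, perm: np.ndarray) -> "GaussianHMMModel":
        """Relabel states: new state i is old state perm[i] (0-based perm)."""
        perm = np.asarray(perm)
        return GaussianHMMModel(
            K=self.K,
            means=self.means[perm],
            covariances=self.covariances[perm],
            transition=self.transition[np.ix_(perm, perm)],
            initial=self.initial[perm],
            fit_score=self.fit_score,
            n_iterations=self.n_iterations,
            seed=self.seed,
            reduction=self.reduction,
            converged=self.converged,
            loglik_trace=self.loglik_trace,
        )

    # -------------------------------------------------------------- I/O

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("means", data=self.means)
            f.create_dataset("covariances", data=self.covariances)
            f.create_dataset("transition", data=self.transition)
            f.create_dataset("initial", data=self.initial)
            f.attrs["K"] = self.K
            f.attrs["fit_score"] = self.fit_score
            f.attrs["n_iterations"] = self.n_iterations
            f.attrs["seed"] = -1 if self.seed is None else self.seed
            f.attrs["converged"] = self.converged
            if self.reduction is not None:
                g = f.create_group("reduction")
                g.create_dataset("loadings", data=self.reduction.loadings)
                g.create_dataset("channel_means", data=self.reduction.channel_means)
                g.create_dataset(
                    "explained_fraction", data=self.reduction.explained_fraction
                )

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "GaussianHMMModel":
        with h5py.File(path, "r") as f:
            reduction = None
            if "reduction" in f:
                g = f["reduction"]
                reduction = PCAReduction(
                    loadings=g["loadings"][()],
                    channel_means=g["channel_means"][()],
                    explained_fraction=g["explained_fraction"][()],
                    n_components=g["loadings"].shape[1],
                )
            seed = int(f.attrs["seed"])
            return cls(
                K=int(f.attrs["K"]),
                means=f["means"][()],
                covariances=f["covariances"][()],
                transition=f["transition"][()],
                initial=f["initial"][()],
                fit_score=float(f.attrs["fit_score"]),
                n_iterations=int(f.attrs["n_iterations"]),
                seed=None if seed < 0 else seed,
                reduction=reduction,
                converged=bool(f.attrs["converged"]),
            )


@dataclass
class StatePath:
    """Decoded 1-based state sequence aligned to one block."""

    states: np.ndarray
    block_id: str = ""
    rate: float = 1.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)

    def __len__(self) -> int:
        return self.states.size


# --------------------------------------------------------------------------
# emission densities


def _log_gaussian(X: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Per-state Gaussian log density for every row of X: returns T x K."""
    T, d = X.shape
    K = means.shape[0]
    out = np.empty((T, K))
    for k in range(K):
        L = np.linalg.cholesky(covs[k])
        diff = X - means[k]
        y = solve_triangular(L, diff.T, lower=True)  # d x T
        maha = np.sum(y**2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        out[:, k] = -0.5 * (maha + logdet + d * np.log(2.0 * np.pi))
    return out


def _regularize(cov: np.ndarray, reg: float) -> np.ndarray:
    d = cov.shape[0]
    ridge = reg * np.trace(cov) / d
    if ridge <= 0 or not np.isfinite(ridge):
        ridge = reg
    return cov + ridge * np.eye(d)


# --------------------------------------------------------------------------
# EM (Baum–Welch) with batching over equal-length blocks


def _group_by_length(blocks: list[np.ndarray]) -> dict[int, list[int]]:
    groups: dict[int, list[int]] = {}
    for i, b in enumerate(blocks):
        groups.setdefault(b.shape[0], []).append(i)
    return groups


def _e_step(
    blocks: list[np.ndarray],
    means: np.ndarray,
    covs: np.ndarray,
    transition: np.ndarray,
    initial: np.ndarray,
):
    """Scaled batched forward–backward over all blocks.

    Returns total log-likelihood and the EM sufficient statistics:
    per-timepoint posteriors gamma (concatenated in block order), expected
    transition counts, and the summed first-timepoint posterior.
    """
    K = means.shape[0]
    A = transition
    groups = _group_by_length(blocks)
    total_ll = 0.0
    gammas: list[np.ndarray | None] = [None] * len(blocks)
    xi_sum = np.zeros((K, K))
    gamma0 = np.zeros(K)

    for L, idxs in groups.items():
        B = len(idxs)
        X = np.stack([blocks[i] for i in idxs])  # B x L x d
        logb = _log_gaussian(X.reshape(B * L, -1), means, covs).reshape(B, L, K)
        # per-timepoint max subtracted for linear-domain stability; the
        # subtraction cancels in posteriors and is restored in the loglik
        shift = logb.max(axis=2, keepdims=True)
        b = np.exp(logb - shift)

        alpha = np.empty((B, L, K))
        c = np.empty((B, L))
        a = initial * b[:, 0]
        c[:, 0] = a.sum(axis=1)
        alpha[:, 0] = a / c[:, 0, None]
        for t in range(1, L):
            a = (alpha[:, t - 1] @ A) * b[:, t]
            c[:, t] = a.sum(axis=1)
            alpha[:, t] = a / c[:, t, None]

        beta_t = np.ones((B, K))
        gamma = np.empty((B, L, K))
        gamma[:, L - 1] = alpha[:, L - 1]
        for t in range(L - 2, -1, -1):
            w = b[:, t + 1] * beta_t / c[:, t + 1, None]
            xi_sum += A * (alpha[:, t].T @ w)
            beta_t = w @ A.T
            g = alpha[:, t] * beta_t
            gamma[:, t] = g / g.sum(axis=1, keepdims=True)

        total_ll += float(np.sum(np.log(c)) + np.sum(shift))
        gamma0 += gamma[:, 0].sum(axis=0)
        for j, i in enumerate(idxs):
            gammas[i] = gamma[j]

    return total_ll, gammas, xi_sum, gamma0


def _m_step(
    blocks: list[np.ndarray],
    gammas: list[np.ndarray],
    xi_sum: np.ndarray,
    gamma0: np.ndarray,
    reg: float,
):
    K = gammas[0].shape[1]
    d = blocks[0].shape[1]
    Nk = np.zeros(K)
    sum_x = np.zeros((K, d))
    for X, G in zip(blocks, gammas):
        Nk += G.sum(axis=0)
        sum_x += G.T @ X
    Nk = np.maximum(Nk, 1e-300)
    means = sum_x / Nk[:, None]
    covs = np.zeros((K, d, d))
    for X, G in zip(blocks, gammas):
        for k in range(K):
            diff = X - means[k]
            covs[k] += (diff * G[:, k : k + 1]).T @ diff
    for k in range(K):
        covs[k] = _regularize(covs[k] / Nk[k], reg)
        covs[k] = 0.5 * (covs[k] + covs[k].T)
    rows = xi_sum.sum(axis=1, keepdims=True)
    transition = np.where(rows > 0, xi_sum / np.maximum(rows, 1e-300), 1.0 / K)
    initial = gamma0 / gamma0.sum()
    return means, covs, transition, initial


def _init_params(
    blocks: list[np.ndarray], K: int, rng: np.random.Generator, reg: float
):
    """K-means initialisation of the means; shared global covariance."""
    X = np.vstack(blocks)
    n = X.shape[0]
    sub = X[rng.choice(n, size=min(n, 20_000), replace=False)]
    km = KMeans(
        n_clusters=K,
        n_init=1,
        random_state=int(rng.integers(2**31 - 1)),
        max_iter=100,
    ).fit(sub)
    means = km.cluster_centers_.copy()
    gcov = _regularize(np.cov(X, rowvar=False).reshape(X.shape[1], X.shape[1]), reg)
    covs = np.stack([gcov.copy() for _ in range(K)])
    transition = np.full((K, K), 0.2 / max(K - 1, 1))
    np.fill_diagonal(transition, 0.8 if K > 1 else 1.0)
    initial = np.full(K, 1.0 / K)
    return means, covs, transition, initial


def fit_gaussian_hmm(
    blocks: list[np.ndarray] | StudyDataset,
    K: int,
    n_restarts: int = 5,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    reduction: PCAReduction | None = None,
    reg: float = 1e-6,
) -> GaussianHMMModel:
    """Maximum-likelihood EM fit of a K-state Gaussian HMM to many blocks.

    Blocks are independent sequences sharing one set of parameters.  The
    best of ``n_restarts`` k-means-seeded EM runs (by log-likelihood) is
    returned.  Covariances carry a ridge of ``reg * trace/d`` to prevent
    collapse.  ``tol`` is the relative log-likelihood change declaring
    convergence.  Results are deterministic for a fixed seed.
    """
    if isinstance(blocks, StudyDataset):
        blocks = blocks.matrices()
    blocks = [np.atleast_2d(np.asarray(b, dtype=float)) for b in blocks]
    if not blocks:
        raise ValueError("no blocks to fit")
    d = blocks[0].shape[1]
    if any(b.shape[1] != d for b in blocks):
        raise ValueError("all blocks must share the channel dimension")
    total_T = sum(b.shape[0] for b in blocks)
    if K < 1:
        raise ValueError("K must be >= 1")

    if K == 1:
        # degenerate case: single Gaussian MLE
        X = np.vstack(blocks)
        mean = X.mean(axis=0, keepdims=True)
        cov = _regularize(np.atleast_2d(np.cov(X, rowvar=False)), reg)[None]
        ll = float(_log_gaussian(X, mean, cov).sum())
        return GaussianHMMModel(
            K=1,
            means=mean,
            covariances=cov,
            transition=np.array([[1.0]]),
            initial=np.array([1.0]),
            fit_score=-ll / total_T,
            n_iterations=0,
            seed=seed,
            reduction=reduction,
            loglik_trace=np.array([ll]),
        )

    master = np.random.default_rng(seed)
    best: GaussianHMMModel | None = None
    for _ in range(max(n_restarts, 1)):
        rng = np.random.default_rng(master.integers(2**31 - 1))
        means, covs, transition, initial = _init_params(blocks, K, rng, reg)
        trace: list[float] = []
        prev_ll = -np.inf
        converged = False
        n_iter = 0
        gammas = None
        for n_iter in range(1, max_iter + 1):
            ll, gammas, xi_sum, gamma0 = _e_step(
                blocks, means, covs, transition, initial
            )
            trace.append(ll)
            if np.isfinite(prev_ll) and ll + 1e-8 < prev_ll:
                warnings.warn(
                    f"log-likelihood decreased by {prev_ll - ll:.3g}", stacklevel=2
                )
            if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(prev_ll):
                converged = True
                break
            prev_ll = ll
            means, covs, transition, initial = _m_step(
                blocks, gammas, xi_sum, gamma0, reg
            )
        if not converged:
            warnings.warn(
                f"EM did not converge in {max_iter} iterations", stacklevel=2
            )
        model = GaussianHMMModel(
            K=K,
            means=means,
            covariances=covs,
            transition=transition,
            initial=initial,
            fit_score=-trace[-1] / total_T,
            n_iterations=n_iter,
            seed=seed,
            reduction=reduction,
            converged=converged,
            loglik_trace=np.asarray(trace),
        )
        if best is None or model.fit_score < best.fit_score:
            best = model
    return best


# --------------------------------------------------------------------------
# Viterbi decoding


def viterbi_decode(
    model: GaussianHMMModel,
    block: np.ndarray,
    block_id: str = "",
    rate: float = 1.0,
) -> StatePath:
    """Most probable joint state path, log domain, lowest-index tie-break."""
    X = np.atleast_2d(np.asarray(block, dtype=float))
    if X.shape[1] != model.n_components:
        raise ValueError(
            f"block has {X.shape[1]} dims, model expects {model.n_components}"
        )
    T = X.shape[0]
    with np.errstate(divide="ignore"):
        logA = np.log(model.transition)
        logpi = np.log(model.initial)
    logb = _log_gaussian(X, model.means, model.covariances)
    delta = logpi + logb[0]
    back = np.empty((T, model.K), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + logA  # prev x next
        back[t] = np.argmax(cand, axis=0)  # first max = lowest prev index
        delta = cand[back[t], np.arange(model.K)] + logb[t]
    states = np.empty(T, dtype=np.int64)
    states[T - 1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        states[t] = back[t + 1][states[t + 1]]
    return StatePath(states=states + 1, block_id=block_id, rate=rate)


def path_log_probability(model: GaussianHMMModel, block: np.ndarray, states) -> float:
    """Joint log-probability of a given 1-based path under the model."""
    X = np.atleast_2d(np.asarray(block, dtype=float))
    s = np.asarray(states, dtype=np.int64) - 1
    with np.errstate(divide="ignore"):
        logA = np.log(model.transition)
        logpi = np.log(model.initial)
    logb = _log_gaussian(X, model.means, model.covariances)
    lp = logpi[s[0]] + logb[0, s[0]]
    for t in range(1, s.size):
        lp += logA[s[t - 1], s[t]] + logb[t, s[t]]
    return float(lp)


def decode_study(
    model: GaussianHMMModel, study: StudyDataset, reduced: list[np.ndarray]
) -> list[StatePath]:
    return [
        viterbi_decode(model, X, block_id=b.block_id, rate=b.rate)
        for b, X in zip(study, reduced)
    ]


# --------------------------------------------------------------------------
# state-map back-projection and thresholding


def back_project_state_means(model: GaussianHMMModel) -> np.ndarray:
    """Project state means through the PCA loadings: channels x K.

    Values are signed component loadings — the channel means are *not*
    added back, so the map shows each state's deviation pattern.
    """
    if model.reduction is None:
        raise ValueError("model carries no PCA reduction; cannot back-project")
    return model.reduction.loadings @ model.means.T


def threshold_state_map(state_map: np.ndarray, percentile: float = 70.0) -> np.ndarray:
    """Zero entries below the per-state absolute-value percentile.

    The threshold is the linear-interpolation percentile of |values| within
    each state column; entries with |value| >= threshold survive (ties at
    the threshold are kept).
    """
    if not 0.0 <= percentile < 100.0:
        raise ValueError("percentile must be in [0, 100)")
    M = np.asarray(state_map, dtype=float)
    out = np.zeros_like(M)
    for k in range(M.shape[1]):
        thresh = np.percentile(np.abs(M[:, k]), percentile)
        keep = np.abs(M[:, k]) >= thresh
        out[keep, k] = M[keep, k]
    return out


# --------------------------------------------------------------------------
# K selection


@dataclass
class KSelectionEntry:
    K: int
    fit_score: float
    fo: np.ndarray  # per-state Viterbi fractional occupancy
    inflow: np.ndarray  # w_k = mean over j != k of transition[j, k]
    under_represented: np.ndarray  # bool per state
    over_represented: np.ndarray
    model: GaussianHMMModel


@dataclass
class KSelectionReport:
    """Per-K diagnostics for choosing the state count.

    A state is flagged under-represented when its Viterbi fractional
    occupancy drops below ``fo_floor / K`` and over-represented when its
    mean in-flow from other states exceeds ``inflow_ceiling / K``
    (estimations with such states fit the data poorly).
    """

    entries: list[KSelectionEntry]
    fo_floor: float = 0.5
    inflow_ceiling: float = 2.0

    def best_k(self) -> int:
        """Smallest K with no flags; falls back to fewest flagged states."""
        clean = [e.K for e in self.entries if not (e.under_represented.any() or e.over_represented.any())]
        if clean:
            return min(clean)
        flags = {
            e.K: int(e.under_represented.sum() + e.over_represented.sum())
            for e in self.entries
        }
        return min(flags, key=lambda k: (flags[k], k))

    def summary(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "K": [e.K for e in self.entries],
                "fit_score": [e.fit_score for e in self.entries],
                "n_under": [int(e.under_represented.sum()) for e in self.entries],
                "n_over": [int(e.over_represented.sum()) for e in self.entries],
            }
        )


def scan_k(
    blocks: list[np.ndarray],
    k_values,
    seed: int | None = None,
    n_restarts: int = 2,
    fo_floor: float = 0.5,
    inflow_ceiling: float = 2.0,
    **fit_kwargs,
) -> KSelectionReport:
    """Fit one model per candidate K and flag badly represented states."""
    k_values = list(k_values)
    if any(k < 2 for k in k_values):
        raise ValueError("scan_k requires K >= 2")
    entries = []
    for K in k_values:
        model = fit_gaussian_hmm(
            blocks, K=K, n_restarts=n_restarts, seed=seed, **fit_kwargs
        )
        counts = np.zeros(K)
        total = 0
        for X in blocks:
            path = viterbi_decode(model, X).states
            counts += np.bincount(path - 1, minlength=K)
            total += path.size
        fo = counts / total
        off = model.transition.copy()
        np.fill_diagonal(off, np.nan)
        inflow = np.nanmean(off, axis=0)
        entries.append(
            KSelectionEntry(
                K=K,
                fit_score=model.fit_score,
                fo=fo,
                inflow=inflow,
                under_represented=fo < fo_floor / K,
                over_represented=inflow > inflow_ceiling / K,
                model=model,
            )
        )
    return KSelectionReport(entries=entries, fo_floor=fo_floor, inflow_ceiling=inflow_ceiling)


# --------------------------------------------------------------------------
# label matching (for recovery tests and stability)


def match_states_by_means(
    true_means: np.ndarray, est_means: np.ndarray
) -> np.ndarray:
    """Permutation mapping estimated states onto true states (0-based).

    Hungarian assignment on squared mean distance; returns ``perm`` such
    that estimated state ``perm[i]`` corresponds to true state ``i``.
    """
    from scipy.optimize import linear_sum_assignment

    cost = ((true_means[:, None, :] - est_means[None, :, :]) ** 2).sum(axis=2)
    _, cols = linear_sum_assignment(cost)
    return cols
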