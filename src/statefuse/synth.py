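"""Ground-truthed synthetic brain, stimulus-feature, and cursor-track streams.

The generator emulates the statistical structure the downstream analyses
assume so that every stage is testable without access to human recordings:

* brain blocks are Markov-switching multivariate Gaussian emissions over a
  configurable number of channels, organised into the participant x task
  block structure of a listening study (resting blocks plus control and
  experiment excerpts);
* stimulus streams are 18 named music-information-retrieval feature columns
  at 10 Hz emitted from a 5-regime Gaussian switching model whose regimes
  load preferentially on context-free (acoustic) vs context-dependent
  (structural) columns;
* cursor tracks are 2-D drift-to-target random walks that reset to the
  exact origin at each excerpt onset, mimicking a continuous 2-D rating
  task whose readout is quadrant occupancy.

Every sampler takes an explicit seed or :class:`numpy.random.Generator`;
identical inputs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .datasets import Block, StudyDataset

#: Music feature columns, in conventional extraction order.  The first 14
#: are rapid acoustic descriptors ("context-free"), the last 4 are
#: structural descriptors that require prior context ("context-dependent").
MIR_FEATURES = (
    "Zero Crossing",
    "Roughness",
    "Amplitude",
    "Spectral Flux",
    "Sub-band Flux 1",
    "Sub-band Flux 2",
    "Sub-band Flux 3",
    "Sub-band Flux 4",
    "Sub-band Flux 5",
    "Sub-band Flux 6",
    "Sub-band Flux 7",
    "Sub-band Flux 8",
    "Sub-band Flux 9",
    "Sub-band Flux 10",
    "Pulse Clarity",
    "Mode",
    "Key Clarity",
    "Novelty",
)

CONTEXT_FREE_COLUMNS = MIR_FEATURES[:14]
CONTEXT_DEPENDENT_COLUMNS = MIR_FEATURES[14:]


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# validation helpers


def check_transition(transition: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Validate a row-stochastic matrix, naming the offending row on failure."""
    P = np.asarray(transition, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError(f"transition matrix must be square, got shape {P.shape}")
    if np.any(P < -atol):
        row = int(np.argwhere(P < -atol)[0, 0])
        raise ValueError(f"transition row {row + 1} has a negative entry")
    sums = P.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > atol)
    if bad.size:
        raise ValueError(
            f"transition row {bad[0] + 1} sums to {sums[bad[0]]:.6f}, expected 1"
        )
    return P


def check_covariances(covs: np.ndarray) -> np.ndarray:
    """Validate symmetry and strict positive definiteness of each matrix."""
    covs = np.asarray(covs, dtype=float)
    for k, S in enumerate(covs):
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError(f"covariance {k + 1} is not symmetric")
        try:
            np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            raise ValueError(f"covariance {k + 1} is not positive definite") from None
    return covs


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left Perron vector)."""
    P = check_transition(transition)
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


# --------------------------------------------------------------------------
# configuration and ground truth


@dataclass
class SynthStudyConfig:
    """Study geometry and generator scale.

    Defaults mirror the emulated listening study: 68 source-space channels,
    40-second blocks at 256 Hz, 17 participants each contributing 10
    resting blocks, 10 control excerpts and 30 experiment excerpts.  Full
    scale is expensive; analyses and tests routinely run reduced
    configurations, which is the intended use of these knobs.
    """

    n_participants: int = 17
    n_excerpts_control: int = 10
    n_excerpts_experiment: int = 30
    n_rest_blocks: int = 10
    n_channels: int = 68
    sample_rate: float = 256.0
    block_duration: float = 40.0
    K_true: int = 4
    separation: float = 5.0  # min pairwise Mahalanobis distance between state means
    stickiness: float = 0.9  # diagonal mass of the generating transition matrix
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_participants,
            self.n_excerpts_control,
            self.n_excerpts_experiment,
            self.n_rest_blocks,
            self.n_channels,
            self.K_true,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if self.sample_rate <= 0 or self.block_duration <= 0:
            raise ValueError("sample_rate and block_duration must be positive")

    @property
    def block_length(self) -> int:
        return int(round(self.sample_rate * self.block_duration))

    @property
    def blocks_per_participant(self) -> int:
        return self.n_rest_blocks + self.n_excerpts_control + self.n_excerpts_experiment


@dataclass
class ConditionEffect:
    """A planted between-condition difference.

    The effect raises the long-run (stationary) fractional occupancy of one
    state by ``delta_fo`` in the named condition, implemented by boosting
    that state's self-transition probability and renormalising its row.
    The boost is solved numerically so the stationary occupancy increases
    by exactly ``delta_fo``.
    """

    state: int  # 1-based
    delta_fo: float
    condition: str = "experiment"

    def describe(self) -> str:
        return (
            f"+{self.delta_fo:g} stationary fractional occupancy of state "
            f"{self.state} in condition {self.condition!r} via self-transition boost"
        )


@dataclass
class GroundTruth:
    """Generative parameters and the latent paths actually sampled."""

    true_transition: np.ndarray
    true_means: np.ndarray  # K x d
    true_covs: np.ndarray  # K x d x d
    true_paths: dict[str, np.ndarray]  # block_id -> 1-based state sequence
    condition_effect: str = "none"
    effect_transition: np.ndarray | None = None  # perturbed matrix, if any

    def __post_init__(self) -> None:
        check_transition(self.true_transition, atol=1e-12)
        check_covariances(self.true_covs)
        K = self.true_transition.shape[0]
        for block_id, p in self.true_paths.items():
            p = np.asarray(p)
            if p.size and (p.min() < 1 or p.max() > K):
                raise ValueError(f"path for {block_id} leaves 1..{K}")

    @property
    def K(self) -> int:
        return self.true_transition.shape[0]


# --------------------------------------------------------------------------
# elementary samplers


def sample_markov_chain(
    transition: np.ndarray,
    initial: np.ndarray,
    length: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Sample a 1-based state sequence from a discrete Markov chain."""
    P = check_transition(transition)
    pi = np.asarray(initial, dtype=float)
    if pi.shape != (P.shape[0],) or abs(pi.sum() - 1.0) > 1e-8 or np.any(pi < 0):
        raise ValueError("initial distribution must be a probability vector over K states")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = _as_rng(seed)
    cum_P = np.cumsum(P, axis=1)
    cum_pi = np.cumsum(pi)
    u = rng.random(length)
    path = np.empty(length, dtype=np.int64)
    state = int(np.searchsorted(cum_pi, u[0], side="right"))
    path[0] = state
    for t in range(1, length):
        state = int(np.searchsorted(cum_P[state], u[t], side="right"))
        path[t] = state
    return path + 1


def emit_gaussian(
    path: np.ndarray,
    means: np.ndarray,
    covs: np.ndarray,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Emit one observation row per path element from its state's Gaussian."""
    path = np.asarray(path)
    means = np.asarray(means, dtype=float)
    covs = np.asarray(covs, dtype=float)
    K, d = means.shape
    if covs.shape != (K, d, d):
        raise ValueError(f"covs must have shape {(K, d, d)}, got {covs.shape}")
    if path.size and (path.min() < 1 or path.max() > K):
        raise ValueError(f"path values must lie in 1..{K}")
    zero_cov = not np.any(covs)
    if not zero_cov:
        check_covariances(covs)
    rng = _as_rng(seed)
    z = rng.standard_normal((path.size, d))
    out = means[path - 1].copy()
    if not zero_cov:
        chols = np.linalg.cholesky(covs)
        for k in range(K):
            idx = np.flatnonzero(path == k + 1)
            if idx.size:
                out[idx] += z[idx] @ chols[k].T
    return out


# --------------------------------------------------------------------------
# condition effects on the transition matrix


def boost_self_transition(transition: np.ndarray, state: int, boost: float) -> np.ndarray:
    """Add ``boost`` to one state's self-transition and renormalise its row."""
    P = check_transition(transition).copy()
    k = state - 1
    new_diag = P[k, k] + boost
    if not (0.0 <= new_diag < 1.0 + 1e-12):
        raise ValueError(
            f"boost {boost:g} drives self-transition of state {state} to "
            f"{new_diag:g}, outside [0, 1]"
        )
    off = 1.0 - P[k, k]
    if off <= 0 and boost != 0:
        raise ValueError(f"state {state} is absorbing; its row cannot be boosted")
    row = P[k].copy()
    row[k] = new_diag
    scale = (1.0 - new_diag) / off if off > 0 else 0.0
    for j in range(P.shape[0]):
        if j != k:
            row[j] = P[k, j] * scale
    P[k] = row
    return check_transition(P, atol=1e-9)


def solve_fo_boost(transition: np.ndarray, state: int, delta_fo: float) -> float:
    """Self-transition boost raising state ``state``'s stationary mass by ``delta_fo``.

    The stationary occupancy of a state is a monotone function of its
    self-transition probability (off-diagonal mass rescaled), so the boost
    is found by bisection on the stationary equation.
    """
    P = check_transition(transition)
    k = state - 1
    base = stationary_distribution(P)[k]
    target = base + delta_fo
    if not (0.0 < target < 1.0):
        raise ValueError(
            f"target occupancy {target:g} for state {state} is not in (0, 1)"
        )

    def gap(b: float) -> float:
        return stationary_distribution(boost_self_transition(P, state, b))[k] - target

    lo = -P[k, k] + 1e-9
    hi = 1.0 - P[k, k] - 1e-9
    if gap(lo) * gap(hi) > 0:
        raise ValueError(
            f"no self-transition boost of state {state} achieves a "
            f"{delta_fo:+g} occupancy change"
        )
    return float(optimize.brentq(gap, lo, hi, xtol=1e-12))


# --------------------------------------------------------------------------
# model construction


def _random_spd(d: int, rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((d, d)) / np.sqrt(d)
    return A @ A.T + np.eye(d)


def _min_pairwise_mahalanobis(means: np.ndarray, pooled_cov: np.ndarray) -> float:
    K = means.shape[0]
    Sinv = np.linalg.inv(pooled_cov)
    best = np.inf
    for i in range(K):
        for j in range(i + 1, K):
            diff = means[i] - means[j]
            best = min(best, float(np.sqrt(diff @ Sinv @ diff)))
    return best


def make_state_model(
    K: int,
    d: int,
    separation: float,
    stickiness: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random sticky transition matrix plus Gaussian emission parameters.

    State means are rescaled so the minimum pairwise Mahalanobis distance
    (with respect to the pooled emission covariance) equals ``separation``.
    """
    P = np.full((K, K), (1.0 - stickiness) / max(K - 1, 1))
    np.fill_diagonal(P, stickiness if K > 1 else 1.0)
    # perturb off-diagonals so rows are distinguishable, then renormalise
    if K > 1:
        jitter = rng.uniform(0.5, 1.5, size=(K, K))
        np.fill_diagonal(jitter, 0.0)
        off = P * jitter
        np.fill_diagonal(off, 0.0)
        row_off = off.sum(axis=1, keepdims=True)
        P = off * ((1.0 - stickiness) / row_off)
        np.fill_diagonal(P, stickiness)
    covs = np.stack([_random_spd(d, rng) for _ in range(K)])
    means = rng.standard_normal((K, d))
    pooled = covs.mean(axis=0)
    current = _min_pairwise_mahalanobis(means, pooled)
    if current <= 0:
        raise RuntimeError("degenerate draw: coincident state means")
    means *= separation / current
    return check_transition(P, atol=1e-9), means, covs


# --------------------------------------------------------------------------
# study-level generators


def generate_brain_study(
    config: SynthStudyConfig,
    effect: ConditionEffect | None = None,
) -> tuple[StudyDataset, GroundTruth]:
    """Generate a full participant x task block collection with ground truth.

    Every participant contributes ``n_rest_blocks`` resting blocks,
    ``n_excerpts_control`` control excerpts and ``n_excerpts_experiment``
    experiment excerpts, in that order.  Excerpt ids are shared across
    participants so stimulus streams can be aligned block-wise.  When a
    condition effect is planted, blocks of the affected condition are
    sampled under the perturbed transition matrix; all other parameters are
    shared.
    """
    rng = np.random.default_rng(config.seed)
    P, means, covs = make_state_model(
        config.K_true, config.n_channels, config.separation, config.stickiness, rng
    )
    effect_P = None
    if effect is not None:
        if not (1 <= effect.state <= config.K_true):
            raise ValueError(f"effect names state {effect.state}, model has K={config.K_true}")
        boost = solve_fo_boost(P, effect.state, effect.delta_fo)
        effect_P = boost_self_transition(P, effect.state, boost)

    pi = stationary_distribution(P)
    T = config.block_length
    blocks: list[Block] = []
    paths: dict[str, np.ndarray] = {}

    tasks: list[tuple[str, str, str | None]] = []
    for i in range(config.n_rest_blocks):
        tasks.append((f"rest{i + 1:02d}", "rest", None))
    for i in range(config.n_excerpts_control):
        tasks.append((f"ctrl{i + 1:02d}", "control", f"ctrl{i + 1:02d}"))
    for i in range(config.n_excerpts_experiment):
        tasks.append((f"exp{i + 1:02d}", "experiment", f"exp{i + 1:02d}"))

    for p in range(config.n_participants):
        pid = f"sub{p + 1:02d}"
        for task_id, condition, excerpt in tasks:
            use_P = P
            use_pi = pi
            if effect is not None and condition == effect.condition:
                use_P = effect_P
                use_pi = stationary_distribution(effect_P)
            path = sample_markov_chain(use_P, use_pi, T, rng)
            data = emit_gaussian(path, means, covs, rng)
            block = Block(
                data=data,
                participant=pid,
                task_id=task_id,
                condition=condition,
                rate=config.sample_rate,
                excerpt_id=excerpt,
            )
            blocks.append(block)
            paths[block.block_id] = path

    truth = GroundTruth(
        true_transition=P,
        true_means=means,
        true_covs=covs,
        true_paths=paths,
        condition_effect=effect.describe() if effect is not None else "none",
        effect_transition=effect_P,
    )
    return StudyDataset(blocks), truth


# --------------------------------------------------------------------------
# music features


@dataclass
class MusicSet:
    """Per-piece feature matrices with the latent regime paths that made them."""

    features: list[pd.DataFrame]  # one timepoints x 18 frame per piece
    piece_ids: list[str]
    true_paths: list[np.ndarray]  # 1-based regime sequences
    transition: np.ndarray
    means: np.ndarray
    covs: np.ndarray
    rate: float = 10.0


def generate_music_features(
    n_pieces: int,
    durations: Sequence[float] | float = 40.0,
    seed: int | np.random.Generator | None = None,
    K: int = 5,
    separation: float = 6.0,
    stickiness: float = 0.9,
    noise_scale: float = 1.0,
    piece_ids: Sequence[str] | None = None,
    rate: float = 10.0,
) -> MusicSet:
    """Emit 18-column feature streams from a K-regime Gaussian switching model.

    The first three regimes place their mean structure on the context-free
    (acoustic) columns; the remaining regimes load on the context-dependent
    (structural) columns.  Durations that are not an integral number of
    frames are rounded down.
    """
    if n_pieces < 1:
        raise ValueError("n_pieces must be >= 1")
    if np.isscalar(durations):
        durations = [float(durations)] * n_pieces
    if len(durations) != n_pieces:
        raise ValueError("need one duration per piece")
    rng = _as_rng(seed)
    d = len(MIR_FEATURES)

    # regime means: context-free regimes vary acoustic columns, the rest
    # vary structural columns; scaled to the requested separation
    means = np.zeros((K, d))
    n_free = min(3, K)
    free_idx = np.arange(14)
    dep_idx = np.arange(14, 18)
    for k in range(K):
        idx = free_idx if k < n_free else dep_idx
        means[k, idx] = rng.standard_normal(idx.size)
    covs = np.stack([noise_scale * _random_spd(d, rng) / d for _ in range(K)])
    if np.any(covs):
        pooled = covs.mean(axis=0)
        current = _min_pairwise_mahalanobis(means, pooled)
        means *= separation / current
    P = np.full((K, K), (1.0 - stickiness) / max(K - 1, 1))
    np.fill_diagonal(P, stickiness)
    pi = stationary_distribution(P)

    if piece_ids is None:
        piece_ids = [f"piece{i + 1:02d}" for i in range(n_pieces)]
    features, paths = [], []
    for i in range(n_pieces):
        T = int(durations[i] * rate)  # non-integral frame counts round down
        path = sample_markov_chain(P, pi, T, rng)
        X = emit_gaussian(path, means, covs, rng)
        features.append(pd.DataFrame(X, columns=list(MIR_FEATURES)))
        paths.append(path)
    return MusicSet(
        features=features,
        piece_ids=list(piece_ids),
        true_paths=paths,
        transition=P,
        means=means,
        covs=covs,
        rate=rate,
    )


# --------------------------------------------------------------------------
# mouse (cursor) tracks


#: unit target point for each quadrant of the rating plane
_QUADRANT_TARGETS = {
    1: np.array([1.0, 1.0]),
    2: np.array([-1.0, 1.0]),
    3: np.array([-1.0, -1.0]),
    4: np.array([1.0, -1.0]),
}


@dataclass
class MouseCoupling:
    """Drift-to-quadrant coupling for a subgroup of participants.

    Participants listed in ``participants`` (all, when ``None``) drift
    toward ``target_quadrant`` with mean-reversion rate ``drift`` (1/s)
    during blocks of ``condition`` (all excerpt conditions when ``None``).
    Uncoupled participants perform an undirected smoothed walk.
    """

    target_quadrant: int
    participants: Sequence[str] | None = None
    condition: str | None = None
    drift: float = 1.0

    def __post_init__(self) -> None:
        if self.target_quadrant not in _QUADRANT_TARGETS:
            raise ValueError("target_quadrant must be 1..4")


def generate_mouse_tracks(
    study: StudyDataset,
    coupling: MouseCoupling | None = None,
    seed: int | np.random.Generator | None = None,
    rate: float = 10.0,
    step: float = 0.15,
    duration: float | None = None,
    max_hold_s: float = 1.0,
    recenter_rate: float = 0.1,
) -> dict[tuple[str, str], pd.DataFrame]:
    """One cursor track per (participant, excerpt): columns time_s, x, y.

    Tracks start at exactly (0, 0) — the rating cursor resets to the centre
    of the axes at each excerpt onset — and hold there for a random
    reaction time (uniform up to ``max_hold_s`` seconds) before evolving as
    an Ornstein–Uhlenbeck style walk: drift toward the coupled quadrant's
    target point when coupling applies, otherwise weak reversion to the
    centre so tracks stay on-screen.  Raters occasionally snap the cursor
    back to the neutral centre (``recenter_rate`` events per second), so
    neutral-state visits vary across excerpts.  ``step`` is the
    per-sqrt-second noise scale; ``step = 0`` with no coupling leaves the
    cursor parked at the origin.
    """
    rng = _as_rng(seed)
    dt = 1.0 / rate
    tracks: dict[tuple[str, str], pd.DataFrame] = {}
    for block in study:
        if block.excerpt_id is None:
            continue  # resting blocks have no rating task
        T = (
            int(round(duration * rate))
            if duration is not None
            else int(round(block.n_timepoints / block.rate * rate))
        )
        coupled = (
            coupling is not None
            and (coupling.participants is None or block.participant in coupling.participants)
            and (coupling.condition is None or block.condition == coupling.condition)
        )
        target = _QUADRANT_TARGETS[coupling.target_quadrant] if coupled else np.zeros(2)
        theta = coupling.drift if coupled else 0.2
        xy = np.zeros((T, 2))
        noise = rng.standard_normal((T, 2))
        recenter = rng.random(T) < recenter_rate * dt
        hold = int(rng.integers(1, max(2, int(round(rate * max_hold_s)) + 1)))
        hold = min(hold, T)
        for t in range(hold, T):
            if recenter[t]:
                continue  # cursor snapped back to the exact centre
            prev = xy[t - 1]
            xy[t] = prev + theta * (target - prev) * dt + step * np.sqrt(dt) * noise[t]
        tracks[(block.participant, block.excerpt_id)] = pd.DataFrame(
            {"time_s": np.arange(T) * dt, "x": xy[:, 0], "y": xy[:, 1]}
        )
    return tracks


def empirical_fo_from_paths(
    truth: GroundTruth, study: StudyDataset, condition: str
) -> np.ndarray:
    """Mean empirical state occupancy over all true paths of one condition.

    This is the generator's sanity channel: a planted condition effect must
    be visible here, before any model fitting.
    """
    K = truth.K
    rows = []
    for block in study:
        if block.condition != condition:
            continue
        path = truth.true_paths[block.block_id]
        rows.append(np.bincount(path - 1, minlength=K) / path.size)
    if not rows:
        raise ValueError(f"no blocks with condition {condition!r}")
    return np.mean(rows, axis=0)
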