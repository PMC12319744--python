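"""Temporal state metrics: occupancy, visits, lifetimes, transitions.

All metrics operate on 1-based integer state paths.  A *visit* is a
maximal run of identical consecutive states; a state's *lifetime* is the
mean length of its visits.  Never-visited states have a genuinely zero
fractional occupancy but an *undefined* (NaN) mean lifetime and an
undefined transition row — NaN marks are explicit and never silently
zeroed.  The conservation identity

    sum_k visits_k * lifetimes_k = T        (samples)

holds exactly for every path, with the 0 * undefined = 0 convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmm import StatePath


def _as_path(path) -> np.ndarray:
    if isinstance(path, StatePath):
        path = path.states
    p = np.asarray(path, dtype=np.int64)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("path must be a non-empty 1-D integer sequence")
    if p.min() < 1:
        raise ValueError("state indices are 1-based; found value < 1")
    return p


def _runs(path: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encoding: (state of each run, length of each run)."""
    change = np.flatnonzero(np.diff(path) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [path.size]))
    return path[starts], ends - starts


def fractional_occupancy(path, K: int) -> np.ndarray:
    """Proportion of samples spent in each state; sums to one."""
    p = _as_path(path)
    if p.max() > K:
        raise ValueError(f"path contains state {p.max()} > K={K}")
    return np.bincount(p - 1, minlength=K) / p.size


def visit_count(path, K: int) -> np.ndarray:
    """Number of maximal runs of each state (runs touching edges count)."""
    p = _as_path(path)
    if p.max() > K:
        raise ValueError(f"path contains state {p.max()} > K={K}")
    states, _ = _runs(p)
    return np.bincount(states - 1, minlength=K).astype(float)


def mean_lifetime(path, K: int, rate: float | None = None) -> np.ndarray:
    """Mean visit duration per state, in samples (or seconds given a rate).

    States with zero visits get NaN (undefined), never zero.
    """
    p = _as_path(path)
    if p.max() > K:
        raise ValueError(f"path contains state {p.max()} > K={K}")
    states, lengths = _runs(p)
    total = np.bincount(states - 1, weights=lengths, minlength=K)
    n = np.bincount(states - 1, minlength=K)
    out = np.full(K, np.nan)
    visited = n > 0
    out[visited] = total[visited] / n[visited]
    if rate is not None:
        out = out / rate
    return out


def transition_matrix(path, K: int) -> np.ndarray:
    """Empirical next-state probabilities, self-transitions included.

    Entry (j, k) is the count of j->k steps divided by the occupancy of j
    over positions 1..T-1.  Rows of states never occupied before the final
    sample are undefined (NaN).
    """
    p = _as_path(path)
    if p.max() > K:
        raise ValueError(f"path contains state {p.max()} > K={K}")
    if p.size < 2:
        raise ValueError("transition matrix requires a path of length >= 2")
    counts = transition_counts(p, K)
    rows = counts.sum(axis=1)
    out = np.full((K, K), np.nan)
    defined = rows > 0
    out[defined] = counts[defined] / rows[defined, None]
    return out


def transition_counts(path, K: int) -> np.ndarray:
    """Raw counts of consecutive j->k steps (the numerator of the matrix)."""
    p = _as_path(path)
    if p.max() > K:
        raise ValueError(f"path contains state {p.max()} > K={K}")
    counts = np.zeros((K, K))
    np.add.at(counts, (p[:-1] - 1, p[1:] - 1), 1.0)
    return counts


def vectorize_transitions(matrix: np.ndarray) -> np.ndarray:
    """Row-major flattening of a square matrix; NaN marks propagate."""
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("expected a square matrix")
    return M.reshape(-1)


def unvectorize_transitions(vector: np.ndarray) -> np.ndarray:
    v = np.asarray(vector, dtype=float)
    K = int(round(np.sqrt(v.size)))
    if K * K != v.size:
        raise ValueError("vector length is not a perfect square")
    return v.reshape(K, K)


# --------------------------------------------------------------------------
# per-block bundles and condition aggregation


@dataclass
class StateMetricSet:
    """All temporal metrics for one block's state path."""

    fo: np.ndarray
    visits: np.ndarray
    lifetimes: np.ndarray  # samples
    transition: np.ndarray  # NaN rows where undefined
    K: int
    n_samples: int
    rate: float = 1.0
    block_id: str = ""
    participant: str = ""
    condition: str = ""
    excerpt_id: str | None = None
    transition_n: np.ndarray | None = None  # raw step counts behind `transition`

    @property
    def lifetimes_seconds(self) -> np.ndarray:
        return self.lifetimes / self.rate


def compute_metrics(
    path,
    K: int,
    rate: float = 1.0,
    block_id: str = "",
    participant: str = "",
    condition: str = "",
    excerpt_id: str | None = None,
) -> StateMetricSet:
    p = _as_path(path)
    if isinstance(path, StatePath):
        rate = path.rate or rate
        block_id = block_id or path.block_id
    return StateMetricSet(
        fo=fractional_occupancy(p, K),
        visits=visit_count(p, K),
        lifetimes=mean_lifetime(p, K),
        transition=transition_matrix(p, K) if p.size >= 2 else np.full((K, K), np.nan),
        K=K,
        n_samples=p.size,
        rate=rate,
        block_id=block_id,
        participant=participant,
        condition=condition,
        excerpt_id=excerpt_id,
        transition_n=transition_counts(p, K) if p.size >= 2 else None,
    )


@dataclass
class ConditionMatrix:
    """Participant-row matrix of block-averaged values for one condition."""

    values: pd.DataFrame  # index: participant id, columns: named metric columns
    condition: str
    metric: str
    K: int

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="participant")


def _metric_columns(metric: str, K: int) -> list[str]:
    if metric == "transition":
        return [
            f"trans_{j + 1:02d}_{k + 1:02d}" for j in range(K) for k in range(K)
        ]
    return [f"{metric}_state{k + 1:02d}" for k in range(K)]


def aggregate_by_condition(
    metric_sets: list[StateMetricSet],
) -> dict[str, dict[str, ConditionMatrix]]:
    """Average per-block metrics into participant x state condition matrices.

    Scalar metrics (fo, visits) average plainly over a participant's blocks
    of each condition.  Lifetimes average weighted by visit counts, so
    blocks where a state was never visited (undefined lifetime) drop out of
    that state's average.  Transition rows average per-block probabilities
    weighted by each block's step counts, which equals pooling the counts
    across blocks before normalising.
    Raises when a participant has no block in a condition that other
    participants do have.
    """
    if not metric_sets:
        raise ValueError("no metric sets to aggregate")
    K = metric_sets[0].K
    if any(m.K != K for m in metric_sets):
        raise ValueError("metric sets disagree on K")
    participants: list[str] = []
    for m in metric_sets:
        if not m.participant or not m.condition:
            raise ValueError(f"block {m.block_id!r} lacks participant/condition labels")
        if m.participant not in participants:
            participants.append(m.participant)
    conditions: list[str] = []
    for m in metric_sets:
        if m.condition not in conditions:
            conditions.append(m.condition)

    by_pc: dict[tuple[str, str], list[StateMetricSet]] = {}
    for m in metric_sets:
        by_pc.setdefault((m.participant, m.condition), []).append(m)
    for cond in conditions:
        missing = [p for p in participants if (p, cond) not in by_pc]
        if missing:
            raise ValueError(
                f"participants with zero blocks in condition {cond!r}: {missing}"
            )

    out: dict[str, dict[str, ConditionMatrix]] = {
        "fo": {},
        "visits": {},
        "lifetimes": {},
        "transition": {},
    }
    for cond in conditions:
        fo_rows, visit_rows, life_rows, trans_rows = [], [], [], []
        for p in participants:
            sets = by_pc[(p, cond)]
            fo_rows.append(np.mean([m.fo for m in sets], axis=0))
            visit_rows.append(np.mean([m.visits for m in sets], axis=0))
            # count-weighted lifetime average, undefined entries excluded
            tot_time = np.zeros(K)
            tot_visits = np.zeros(K)
            for m in sets:
                v = m.visits
                lt = np.where(v > 0, m.lifetimes, 0.0)
                tot_time += v * lt
                tot_visits += v
            life = np.full(K, np.nan)
            seen = tot_visits > 0
            life[seen] = tot_time[seen] / tot_visits[seen]
            life_rows.append(life)
            # count-weighted average of per-block transition matrices
            # (identical to pooling step counts before normalising)
            pooled = np.zeros((K, K))
            for m in sets:
                if m.transition_n is not None:
                    pooled += m.transition_n
            trans_avg = np.full((K, K), np.nan)
            rows_n = pooled.sum(axis=1)
            rows_seen = rows_n > 0
            trans_avg[rows_seen] = pooled[rows_seen] / rows_n[rows_seen, None]
            trans_rows.append(vectorize_transitions(trans_avg))
        idx = pd.Index(participants, name="participant")
        out["fo"][cond] = ConditionMatrix(
            pd.DataFrame(fo_rows, index=idx, columns=_metric_columns("fo", K)),
            cond, "fo", K,
        )
        out["visits"][cond] = ConditionMatrix(
            pd.DataFrame(visit_rows, index=idx, columns=_metric_columns("visits", K)),
            cond, "visits", K,
        )
        out["lifetimes"][cond] = ConditionMatrix(
            pd.DataFrame(life_rows, index=idx, columns=_metric_columns("lifetimes", K)),
            cond, "lifetimes", K,
        )
        out["transition"][cond] = ConditionMatrix(
            pd.DataFrame(trans_rows, index=idx, columns=_metric_columns("transition", K)),
            cond, "transition", K,
        )
    return out


# --------------------------------------------------------------------------
# cross-modal correlation blocks


def correlate_blocks(
    A: dict[str, np.ndarray],
    B: dict[str, np.ndarray],
    a_names: list[str] | None = None,
    b_names: list[str] | None = None,
) -> pd.DataFrame:
    """Within-participant Pearson correlations across matched items.

    ``A[pid]`` is an items x p matrix and ``B[pid]`` an items x q matrix
    with the same item (excerpt) axis.  For each participant every
    (A-column, B-column) pair is correlated across items, giving one row of
    p*q correlations per participant (columns ordered A-major).
    Zero-variance columns yield NaN correlations, to be excluded
    downstream.
    """
    if set(A) != set(B):
        raise ValueError("A and B must cover the same participants")
    pids = list(A)
    first = next(iter(A.values()))
    p = first.shape[1]
    q = next(iter(B.values())).shape[1]
    if a_names is None:
        a_names = [f"a{i + 1:02d}" for i in range(p)]
    if b_names is None:
        b_names = [f"b{i + 1:02d}" for i in range(q)]
    cols = [f"{an}*{bn}" for an in a_names for bn in b_names]
    rows = []
    for pid in pids:
        X, Y = np.asarray(A[pid], float), np.asarray(B[pid], float)
        if X.shape[0] != Y.shape[0]:
            raise ValueError(f"participant {pid}: item axes differ")
        if X.shape[0] < 3:
            raise ValueError(f"participant {pid}: need >= 3 items to correlate")
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        sx = Xc.std(axis=0)
        sy = Yc.std(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            R = (Xc.T @ Yc) / X.shape[0] / np.outer(sx, sy)
        R[~np.isfinite(R)] = np.nan
        rows.append(R.reshape(-1))
    return pd.DataFrame(rows, index=pd.Index(pids, name="participant"), columns=cols)
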