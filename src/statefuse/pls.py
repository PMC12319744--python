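"""Partial least squares by SVD, with permutation and bootstrap inference.

Two PLS flavours are implemented:

* **Mean-centred PLS** decomposes the deviation of condition means from
  their grand mean.  Each latent variable (LV) pairs a condition contrast
  (design salience) with a pattern over variables (variable salience) and
  a singular value summarising the covariance explained.
* **Behavioural PLS** (PLS correlation) decomposes the stacked
  per-condition correlation matrices between a variable matrix X and a
  behaviour matrix Y, expressing multivariate X–Y correlation patterns.

Significance of each LV is assessed by permutation (condition labels for
mean-centred; row order of Y within condition for behavioural), with the
add-one smoothing convention p = (1 + #{perm >= obs}) / (n_perm + 1).
Reliability is assessed by bootstrap resampling of participants (a
participant's rows move together across conditions); each replicate is
aligned to the original solution — Procrustes matching restricted to LV
reordering and sign flips — before standard errors are accumulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: bootstrap ratios are capped at this magnitude when the SE underflows
MAX_BOOTSTRAP_RATIO = 1e6


@dataclass
class PLSResult:
    """One PLS decomposition with its resampling statistics."""

    mode: str  # "mean_centered" | "behavioral"
    singular_values: np.ndarray  # descending, >= 0
    design_saliences: np.ndarray  # conditions (or behaviour rows) x LV
    variable_saliences: np.ndarray  # variables x LV
    scores: np.ndarray  # data rows x LV
    condition_order: list[str]
    variable_names: list[str] = field(default_factory=list)
    design_names: list[str] = field(default_factory=list)
    perm_p: np.ndarray | None = None
    bootstrap_ratios: np.ndarray | None = None  # variables x LV
    ci_low: np.ndarray | None = None  # design saliences, 95% percentile CI
    ci_high: np.ndarray | None = None
    n_perm: int = 0
    n_boot: int = 0
    seed: int | None = None

    @property
    def n_lv(self) -> int:
        return self.singular_values.size

    def covariance_explained(self) -> np.ndarray:
        s2 = self.singular_values**2
        return s2 / s2.sum() if s2.sum() > 0 else s2

    def lv_table(self, lv: int = 0) -> pd.DataFrame:
        """Human-readable per-variable summary of one LV."""
        names = self.variable_names or [
            f"var{i + 1:03d}" for i in range(self.variable_saliences.shape[0])
        ]
        tbl = pd.DataFrame(
            {
                "variable": names,
                "salience": self.variable_saliences[:, lv],
            }
        )
        if self.bootstrap_ratios is not None:
            tbl["bootstrap_ratio"] = self.bootstrap_ratios[:, lv]
        return tbl


# --------------------------------------------------------------------------
# decomposition cores


def _condition_order(labels: np.ndarray) -> list[str]:
    seen: dict[str, None] = {}
    for l in labels:
        seen.setdefault(str(l), None)
    return list(seen)


def _drop_constant_columns(X: np.ndarray, names: list[str]):
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        # fully label-invariant data: keep the zero decomposition defined
        return X, names, np.ones(X.shape[1], dtype=bool)
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping constant columns: {dropped[:8]}"
                      + ("..." if len(dropped) > 8 else ""), stacklevel=3)
    return X[:, keep], [n for n, k in zip(names, keep) if k], keep


def _mean_centered_deviations(
    X: np.ndarray, labels: np.ndarray, order: list[str]
) -> np.ndarray:
    """Condition means minus the unweighted grand mean of condition means."""
    M = np.stack([X[labels == c].mean(axis=0) for c in order])
    return M - M.mean(axis=0)


def _svd(D: np.ndarray):
    U, s, Vt = np.linalg.svd(D, full_matrices=False)
    return U, s, Vt.T


def _zscore_within(X: np.ndarray, labels: np.ndarray, order: list[str]) -> np.ndarray:
    Z = np.empty_like(X, dtype=float)
    for c in order:
        rows = labels == c
        mu = X[rows].mean(axis=0)
        sd = X[rows].std(axis=0)
        sd[sd == 0] = 1.0
        Z[rows] = (X[rows] - mu) / sd
    return Z


def _correlation_stack(
    X: np.ndarray, Y: np.ndarray, labels: np.ndarray, order: list[str]
) -> np.ndarray:
    """Vertically stacked per-condition corr(Y, X) matrices (q x p each)."""
    blocks = []
    n_rows_min = min(int((labels == c).sum()) for c in order)
    if n_rows_min < 3:
        raise ValueError("behavioural PLS needs >= 3 rows per condition")
    for c in order:
        rows = labels == c
        Xz = _zscore_within(X[rows], np.zeros(rows.sum()), [0])
        Yz = _zscore_within(Y[rows], np.zeros(rows.sum()), [0])
        blocks.append(Yz.T @ Xz / rows.sum())
    return np.vstack(blocks)


# --------------------------------------------------------------------------
# Procrustes alignment


def _procrustes_rotation(reference: np.ndarray, replicate: np.ndarray) -> np.ndarray:
    """Orthogonal R minimising ||replicate @ R - reference||_F."""
    U, _, Vt = np.linalg.svd(replicate.T @ reference)
    return U @ Vt


def procrustes_align(reference: np.ndarray, replicate: np.ndarray) -> np.ndarray:
    """Rotate (and thus sign/order correct) replicate saliences onto a reference."""
    if reference.shape != replicate.shape:
        raise ValueError("reference and replicate must share a shape")
    return replicate @ _procrustes_rotation(reference, replicate)


def _signed_permutation(reference: np.ndarray, replicate: np.ndarray) -> np.ndarray:
    """Signed-permutation matrix matching replicate LVs to reference LVs.

    The bootstrap restricts Procrustes alignment to the signed-permutation
    subgroup: a full orthogonal rotation would absorb genuine sampling
    variability (and, for square salience matrices, map every replicate
    exactly onto the reference, zeroing the bootstrap SE).  LV axes are
    matched greedily by absolute inner product, then sign-corrected.
    """
    C = replicate.T @ reference  # replicate-LV x reference-LV
    L = C.shape[0]
    P = np.zeros((L, L))
    work = np.abs(C.astype(float))
    for _ in range(L):
        i, j = np.unravel_index(np.argmax(work), work.shape)
        P[i, j] = np.sign(C[i, j]) or 1.0
        work[i, :] = -np.inf
        work[:, j] = -np.inf
    return P


# --------------------------------------------------------------------------
# resampling engines


def _permutation_pvalues_core(observed_s, perm_draw, n_perm, rng):
    exceed = np.zeros(observed_s.size)
    for _ in range(n_perm):
        s_perm = perm_draw(rng)
        L = min(s_perm.size, observed_s.size)
        exceed[:L] += s_perm[:L] >= observed_s[:L] - 1e-12
    return (1.0 + exceed) / (n_perm + 1.0)


def _participant_bootstrap_indices(
    labels: np.ndarray,
    participants: np.ndarray,
    order: list[str],
    rng: np.random.Generator,
    max_redraw: int = 100,
) -> np.ndarray:
    """Row indices resampling participants with replacement.

    One draw of participant ids is shared across conditions, so every row
    belonging to a drawn participant moves into the replicate together.
    Degenerate draws (fewer than two unique participants) are redrawn.
    """
    uniq: list = []
    for p in participants:
        if p not in uniq:
            uniq.append(p)
    uniq_arr = np.asarray(uniq, dtype=object)
    for _ in range(max_redraw):
        draw = uniq_arr[rng.integers(0, len(uniq), size=len(uniq))]
        if len(set(draw.tolist())) >= 2:
            rows = []
            for c in order:
                for p in draw:
                    rows.extend(
                        np.flatnonzero((labels == c) & (participants == p)).tolist()
                    )
            return np.asarray(rows, dtype=int)
    raise RuntimeError("bootstrap kept drawing degenerate resamples")


# --------------------------------------------------------------------------
# public operations


def mean_centered_pls(
    X: np.ndarray | pd.DataFrame,
    conditions,
    n_perm: int = 500,
    n_boot: int = 100,
    seed: int | None = None,
    participants=None,
) -> PLSResult:
    """Mean-centred PLS over rows grouped by condition.

    Rows of ``X`` are observations (typically one row per participant per
    condition); the decomposition is the SVD of the conditions x variables
    matrix of condition-mean deviations from the unweighted grand mean.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xa = np.asarray(X, dtype=float)
    labels = np.asarray([str(c) for c in conditions])
    if Xa.shape[0] != labels.size:
        raise ValueError("one condition label per row is required")
    order = _condition_order(labels)
    if len(order) < 2:
        raise ValueError("mean-centred PLS needs >= 2 conditions")
    for c in order:
        if (labels == c).sum() < 2:
            warnings.warn(f"condition {c!r} has a single row", stacklevel=2)
    if names is None:
        names = [f"var{i + 1:03d}" for i in range(Xa.shape[1])]
    Xa, names, _ = _drop_constant_columns(Xa, names)

    D = _mean_centered_deviations(Xa, labels, order)
    U, s, V = _svd(D)
    grand = np.stack([Xa[labels == c].mean(axis=0) for c in order]).mean(axis=0)
    scores = (Xa - grand) @ V

    rng = np.random.default_rng(seed)
    perm_p = None
    if n_perm > 0:
        def draw(r: np.random.Generator) -> np.ndarray:
            perm_labels = labels[r.permutation(labels.size)]
            Dp = _mean_centered_deviations(Xa, perm_labels, order)
            return np.linalg.svd(Dp, compute_uv=False)

        perm_p = _permutation_pvalues_core(s, draw, n_perm, rng)

    br = ci_low = ci_high = None
    if n_boot > 0:
        parts = (
            np.asarray(participants, dtype=object)
            if participants is not None
            else np.asarray([f"row{i}" for i in range(Xa.shape[0])], dtype=object)
        )
        V_reps = np.empty((n_boot,) + V.shape)
        U_reps = np.empty((n_boot,) + U.shape)
        for b in range(n_boot):
            rows = _participant_bootstrap_indices(labels, parts, order, rng)
            Db = _mean_centered_deviations(Xa[rows], labels[rows], order)
            Ub, sb, Vb = _svd(Db)
            P = _signed_permutation(V, Vb)
            V_reps[b] = Vb @ P
            U_reps[b] = Ub @ P
        se = V_reps.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            br = V / se
        br = np.where(np.isfinite(br), br, np.sign(V) * MAX_BOOTSTRAP_RATIO)
        br = np.clip(br, -MAX_BOOTSTRAP_RATIO, MAX_BOOTSTRAP_RATIO)
        ci_low = np.percentile(U_reps, 2.5, axis=0)
        ci_high = np.percentile(U_reps, 97.5, axis=0)
        ci_low, ci_high = np.minimum(ci_low, U), np.maximum(ci_high, U)

    return PLSResult(
        mode="mean_centered",
        singular_values=s,
        design_saliences=U,
        variable_saliences=V,
        scores=scores,
        condition_order=order,
        variable_names=names,
        design_names=order,
        perm_p=perm_p,
        bootstrap_ratios=br,
        ci_low=ci_low,
        ci_high=ci_high,
        n_perm=n_perm,
        n_boot=n_boot,
        seed=seed,
    )


def behavioral_pls(
    X: np.ndarray | pd.DataFrame,
    Y: np.ndarray | pd.DataFrame,
    conditions=None,
    n_perm: int = 500,
    n_boot: int = 100,
    seed: int | None = None,
    participants=None,
) -> PLSResult:
    """Behavioural PLS (PLS correlation) between matched X and Y rows.

    Per condition, the q x p correlation matrix corr(Y, X) is computed
    across rows; the condition blocks are stacked vertically and decomposed
    by SVD.  Design saliences live on the stacked behaviour rows
    (condition x Y-column), variable saliences on X columns.
    """
    x_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    y_names = list(Y.columns) if isinstance(Y, pd.DataFrame) else None
    Xa = np.asarray(X, dtype=float)
    Ya = np.asarray(Y, dtype=float)
    if Xa.shape[0] != Ya.shape[0]:
        raise ValueError("X and Y must have matched rows")
    if conditions is None:
        conditions = ["all"] * Xa.shape[0]
    labels = np.asarray([str(c) for c in conditions])
    order = _condition_order(labels)
    if x_names is None:
        x_names = [f"x{i + 1:03d}" for i in range(Xa.shape[1])]
    if y_names is None:
        y_names = [f"y{i + 1:03d}" for i in range(Ya.shape[1])]
    Xa, x_names, _ = _drop_constant_columns(Xa, x_names)
    Ya, y_names, _ = _drop_constant_columns(Ya, y_names)

    R = _correlation_stack(Xa, Ya, labels, order)
    U, s, V = _svd(R)
    scores = _zscore_within(Xa, labels, order) @ V
    design_names = [f"{c}:{yn}" for c in order for yn in y_names]

    rng = np.random.default_rng(seed)
    perm_p = None
    if n_perm > 0:
        def draw(r: np.random.Generator) -> np.ndarray:
            # permute Y rows within condition, leaving X fixed
            idx = np.arange(Ya.shape[0])
            for c in order:
                rows = np.flatnonzero(labels == c)
                idx[rows] = rows[r.permutation(rows.size)]
            Rp = _correlation_stack(Xa, Ya[idx], labels, order)
            return np.linalg.svd(Rp, compute_uv=False)

        perm_p = _permutation_pvalues_core(s, draw, n_perm, rng)

    br = ci_low = ci_high = None
    if n_boot > 0:
        parts = (
            np.asarray(participants, dtype=object)
            if participants is not None
            else np.asarray([f"row{i}" for i in range(Xa.shape[0])], dtype=object)
        )
        V_reps = np.empty((n_boot,) + V.shape)
        U_reps = np.empty((n_boot,) + U.shape)
        b = 0
        attempts = 0
        while b < n_boot and attempts < 50 * n_boot:
            attempts += 1
            rows = _participant_bootstrap_indices(labels, parts, order, rng)
            try:
                Rb = _correlation_stack(Xa[rows], Ya[rows], labels[rows], order)
            except ValueError:
                continue
            if not np.all(np.isfinite(Rb)):
                continue  # degenerate resample: a column lost its variance
            Ub, sb, Vb = _svd(Rb)
            P = _signed_permutation(V, Vb)
            V_reps[b] = Vb @ P
            U_reps[b] = Ub @ P
            b += 1
        if b < n_boot:
            raise RuntimeError("bootstrap failed to collect enough valid resamples")
        se = V_reps.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            br = V / se
        br = np.where(np.isfinite(br), br, np.sign(V) * MAX_BOOTSTRAP_RATIO)
        br = np.clip(br, -MAX_BOOTSTRAP_RATIO, MAX_BOOTSTRAP_RATIO)
        ci_low = np.percentile(U_reps, 2.5, axis=0)
        ci_high = np.percentile(U_reps, 97.5, axis=0)
        ci_low, ci_high = np.minimum(ci_low, U), np.maximum(ci_high, U)

    return PLSResult(
        mode="behavioral",
        singular_values=s,
        design_saliences=U,
        variable_saliences=V,
        scores=scores,
        condition_order=order,
        variable_names=x_names,
        design_names=design_names,
        perm_p=perm_p,
        bootstrap_ratios=br,
        ci_low=ci_low,
        ci_high=ci_high,
        n_perm=n_perm,
        n_boot=n_boot,
        seed=seed,
    )


def permutation_pvalues(
    result: PLSResult,
    X,
    Y=None,
    conditions=None,
    n_perm: int = 500,
    seed: int | None = None,
) -> np.ndarray:
    """Standalone permutation test matching a result's decomposition mode."""
    if result.mode == "mean_centered":
        res = mean_centered_pls(X, conditions, n_perm=n_perm, n_boot=0, seed=seed)
    else:
        res = behavioral_pls(X, Y, conditions, n_perm=n_perm, n_boot=0, seed=seed)
    return res.perm_p


def bootstrap_reliability(
    result: PLSResult,
    X,
    Y=None,
    conditions=None,
    n_boot: int = 100,
    seed: int | None = None,
    participants=None,
):
    """Standalone bootstrap matching a result's decomposition mode."""
    if result.mode == "mean_centered":
        res = mean_centered_pls(
            X, conditions, n_perm=0, n_boot=n_boot, seed=seed, participants=participants
        )
    else:
        res = behavioral_pls(
            X, Y, conditions, n_perm=0, n_boot=n_boot, seed=seed, participants=participants
        )
    return res.bootstrap_ratios, res.ci_low, res.ci_high
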