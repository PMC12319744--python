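"""Manual state estimation for 2-D continuous rating (cursor) trajectories.

A cursor track on a two-axis rating plane is mapped to a five-state
sequence: quadrants 1–4 by the sign of (x, y), plus a fifth neutral state
for the exact centre starting position (0, 0), where the cursor rests at
each excerpt onset.  The resulting integer path feeds the same temporal
metrics (fractional occupancy, visits, lifetimes, transitions) as the
model-decoded brain states, so both modalities live in one conceptual
space.

Conventions: Q1 (x>0, y>0), Q2 (x<0, y>0), Q3 (x<0, y<0), Q4 (x>0, y<0).
Points on an axis (exactly one coordinate zero) treat the zero coordinate
as positive, e.g. (0, -2) -> Q4.  Which on-screen quadrant corresponds to
which rating pole (valence/arousal or pitch/tempo) is a labelling choice
left to configuration, not code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import StateMetricSet, compute_metrics

NEUTRAL_STATE = 5


@dataclass
class QuadrantPath:
    """Five-state cursor path: quadrants 1-4 plus the neutral centre (5)."""

    states: np.ndarray
    rate: float = 1.0
    excerpt_id: str | None = None
    participant_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.size and not np.all((self.states >= 1) & (self.states <= 5)):
            raise ValueError("quadrant states must lie in 1..5")

    def __len__(self) -> int:
        return self.states.size


def assign_mouse_states(
    xy: np.ndarray | pd.DataFrame,
    rate: float = 1.0,
    epsilon: float = 0.0,
    excerpt_id: str | None = None,
    participant_id: str = "",
    condition: str = "",
) -> QuadrantPath:
    """Map each (x, y) sample to a quadrant state, (0, 0) to neutral.

    ``epsilon`` optionally widens the neutral region to a disc of that
    radius for noisy pointing hardware; the default 0 keeps neutral as the
    exact origin.  NaN coordinates raise, naming the first bad sample.
    """
    if isinstance(xy, pd.DataFrame):
        if rate == 1.0 and "time_s" in xy.columns and len(xy) > 1:
            dt = float(xy["time_s"].iloc[1] - xy["time_s"].iloc[0])
            if dt > 0:
                rate = 1.0 / dt
        xy = xy[["x", "y"]].to_numpy()
    P = np.asarray(xy, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2:
        raise ValueError("xy must be a timepoints x 2 array")
    bad = ~np.isfinite(P).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite coordinate at sample index {int(np.argmax(bad))}")
    x, y = P[:, 0], P[:, 1]
    states = np.empty(P.shape[0], dtype=np.int64)
    # zero coordinates inherit the positive half-plane
    xpos = x >= 0
    ypos = y >= 0
    states[xpos & ypos] = 1
    states[~xpos & ypos] = 2
    states[~xpos & ~ypos] = 3
    states[xpos & ~ypos] = 4
    if epsilon > 0:
        neutral = x**2 + y**2 <= epsilon**2
    else:
        neutral = (x == 0) & (y == 0)
    states[neutral] = NEUTRAL_STATE
    return QuadrantPath(
        states=states,
        rate=rate,
        excerpt_id=excerpt_id,
        participant_id=participant_id,
        condition=condition,
    )


def behavior_metrics(path: QuadrantPath) -> StateMetricSet:
    """Temporal metrics of a quadrant path, identical in form to brain metrics."""
    return compute_metrics(
        path.states,
        K=5,
        rate=path.rate,
        block_id=path.excerpt_id or "",
        participant=path.participant_id,
        condition=path.condition,
        excerpt_id=path.excerpt_id,
    )


def path_to_csv(path: QuadrantPath, out) -> None:
    t = np.arange(len(path)) / path.rate
    pd.DataFrame({"time_s": t, "state": path.states}).to_csv(out, index=False)


def track_from_csv(src) -> pd.DataFrame:
    df = pd.read_csv(src)
    missing = {"time_s", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"track CSV lacks columns: {sorted(missing)}")
    return df
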