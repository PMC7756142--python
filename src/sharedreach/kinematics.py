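"""Reach segmentation and kinematic statistics.

Per-reach statistics, each defined over the window from target appearance to
target touch:

* ``D``  — reach deviation: hand path length minus the straight-line distance
  between the first and last sample (0 for a perfectly straight reach).
* ``J``  — mean hand jerk: average magnitude of the numerical third
  derivative of position.
* ``RT`` — reaction time: first time hand speed exceeds 10% of its
  within-trial maximum.
* ``TT`` — task time: target appearance to touch.
* ``TE`` — target error: distance from the reach endpoint to the target
  center.
* ``IP`` — inter-participant distance: time-averaged distance between the
  two members' hands, overall and over three equal-duration phases.

Aggregation follows the design of the study being modeled: kinematic
statistics are analyzed at the dyad level (human value = mean of the two
members' per-participant means; the avatar contributes one value per dyad),
ratings at the participant level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSampleError,
    IncompleteDesignError,
    InvalidArgumentError,
    NoTouchError,
)
from .trajectory import TargetSpec, TrajectorySamples

Condition = Literal["solo", "shared"]

AVATAR_ID = "avatar"

METRIC_NAMES = ("D", "J", "RT", "TT", "TE")


@dataclass(frozen=True)
class ReachTrial:
    """One segmented reach: trajectory clipped to [target onset, touch]."""

    dyad_id: int
    participant_id: str  # member id, or "avatar"
    condition: str  # "solo" | "shared"
    session: int  # 1..n within condition
    trial_index: int
    trajectory: TrajectorySamples
    target: TargetSpec
    onset_time: float
    touch_time: float

    def __post_init__(self) -> None:
        if self.condition not in ("solo", "shared"):
            raise InvalidArgumentError(f"unknown condition {self.condition!r}")
        if not self.onset_time < self.touch_time:
            raise InvalidArgumentError("onset_time must precede touch_time")

    @property
    def actor(self) -> str:
        return "avatar" if self.participant_id == AVATAR_ID else "human"


@dataclass(frozen=True)
class TrialMetrics:
    D: float
    J: float
    RT: float
    TT: float
    TE: float


@dataclass(frozen=True)
class IPResult:
    """Inter-participant hand distance: overall and per movement phase.

    ``overall`` equals the duration-weighted mean of the phase values.
    """

    overall: float
    phases: tuple[float, ...]


def segment_reach(
    raw: TrajectorySamples,
    target: TargetSpec,
    *,
    dyad_id: int = 0,
    participant_id: str = "p00",
    condition: str = "solo",
    session: int = 1,
    trial_index: int = 0,
) -> ReachTrial:
    """Clip a raw recording to the reach window [target onset, touch].

    Touch is the first sample at which the hand lies inside the axis-aligned
    target cube, at or after target onset.  Raises :class:`NoTouchError` when
    the hand never enters the cube (callers exclude and count such trials).
    """
    eps = 0.5 * raw.dt
    after_onset = raw.times >= target.onset_time - eps
    if not after_onset.any():
        raise InvalidArgumentError("recording ends before target onset")
    inside = target.contains(raw.positions) & after_onset
    if not inside.any():
        raise NoTouchError("hand never enters the target cube")
    touch_idx = int(np.argmax(inside))
    touch_time = float(raw.times[touch_idx])
    traj = raw.window(target.onset_time, touch_time)
    return ReachTrial(
        dyad_id=dyad_id,
        participant_id=participant_id,
        condition=condition,
        session=session,
        trial_index=trial_index,
        trajectory=traj,
        target=target,
        onset_time=float(target.onset_time),
        touch_time=touch_time,
    )


def reach_deviation(trial: ReachTrial) -> float:
    """Path length minus endpoint chord; >= 0 by the triangle inequality."""
    pos = trial.trajectory.positions
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    chord = float(np.linalg.norm(pos[-1] - pos[0]))
    return float(steps.sum() - chord)


def mean_jerk(trial: ReachTrial) -> float:
    """Mean magnitude of the numerical third derivative of position.

    Uses the third finite difference of position / dt^3 (exactly zero for
    constant-velocity and constant-acceleration motion).  The two boundary
    estimates get 1.5-sample extra weight so the average covers the full
    reach duration rather than only the interior of the stencil.
    """
    pos = trial.trajectory.positions
    if len(pos) < 4:
        raise InvalidArgumentError("mean jerk needs at least 4 samples")
    dt = trial.trajectory.dt
    mags = np.linalg.norm(np.diff(pos, n=3, axis=0), axis=1) / dt**3
    total = mags.sum() + 1.5 * (mags[0] + mags[-1])
    return float(total / len(pos))


def _speed(traj: TrajectorySamples) -> np.ndarray:
    """Hand speed via central differences (one-sided at the ends)."""
    vel = np.gradient(traj.positions, traj.dt, axis=0)
    return np.linalg.norm(vel, axis=1)


def reaction_time(trial: ReachTrial, threshold_frac: float = 0.1) -> float:
    """Time from target onset until speed first exceeds
    ``threshold_frac`` of its within-trial maximum (strict crossing)."""
    speed = _speed(trial.trajectory)
    vmax = float(speed.max())
    if vmax <= 0.0:
        raise DegenerateSampleError("identically zero trajectory: RT undefined")
    above = speed > threshold_frac * vmax
    idx = int(np.argmax(above))
    return float(trial.trajectory.times[idx] - trial.onset_time)


def task_time(trial: ReachTrial) -> float:
    return float(trial.touch_time - trial.onset_time)


def target_error(trial: ReachTrial) -> float:
    endpoint = trial.trajectory.positions[-1]
    return float(np.linalg.norm(endpoint - trial.target.position))


def compute_trial_metrics(trial: ReachTrial) -> TrialMetrics:
    return TrialMetrics(
        D=reach_deviation(trial),
        J=mean_jerk(trial),
        RT=reaction_time(trial),
        TT=task_time(trial),
        TE=target_error(trial),
    )


def interpersonal_distance(
    trial_a: ReachTrial,
    trial_b: ReachTrial,
    n_phases: int = 3,
    window: Literal["later_touch", "earlier_touch"] = "later_touch",
) -> IPResult:
    """Time-averaged hand-to-hand distance between the two members.

    The window runs from the common target onset to the later touch by
    default, holding the earlier finisher at its final position (so the
    equal-duration phases stay well defined); ``window="earlier_touch"``
    truncates at the first touch instead.
    """
    if n_phases < 1:
        raise InvalidArgumentError("n_phases must be >= 1")
    a, b = trial_a.trajectory, trial_b.trajectory
    if abs(a.dt - b.dt) > 1e-9:
        raise InvalidArgumentError("trajectories have different sampling periods")
    onset = max(trial_a.onset_time, trial_b.onset_time)
    if window == "later_touch":
        t_end = max(trial_a.touch_time, trial_b.touch_time)
    elif window == "earlier_touch":
        t_end = min(trial_a.touch_time, trial_b.touch_time)
    else:
        raise InvalidArgumentError(f"unknown window convention {window!r}")
    dt = a.dt
    n = int(round((t_end - onset) / dt)) + 1
    grid = onset + np.arange(n) * dt

    def sample(traj: TrajectorySamples, t: np.ndarray) -> np.ndarray:
        # hold the hand at its final (or first) position outside the record
        tc = np.clip(t, traj.times[0], traj.times[-1])
        return traj.at(tc)

    dist = np.linalg.norm(sample(a, grid) - sample(b, grid), axis=1)
    chunks = np.array_split(dist, n_phases)
    phases = tuple(float(c.mean()) for c in chunks)
    weights = np.array([len(c) for c in chunks], dtype=float)
    overall = float(np.average(phases, weights=weights))
    return IPResult(overall=overall, phases=phases)


# ---------------------------------------------------------------------------
# tables and aggregation

def metrics_table(trials: Iterable[ReachTrial]) -> pd.DataFrame:
    """Tidy per-trial metrics table (one row per segmented reach)."""
    rows = []
    for t in trials:
        m = compute_trial_metrics(t)
        rows.append(
            {
                "dyad_id": t.dyad_id,
                "participant_id": t.participant_id,
                "actor": t.actor,
                "condition": t.condition,
                "session": t.session,
                "trial": t.trial_index,
                "D": m.D,
                "J": m.J,
                "RT": m.RT,
                "TT": m.TT,
                "TE": m.TE,
            }
        )
    return pd.DataFrame(rows)


def aggregate_metrics(
    table: pd.DataFrame,
    level: Literal["participant", "dyad"] = "dyad",
    actor: Literal["human", "avatar"] = "human",
) -> pd.DataFrame:
    """Per-unit condition means of every metric.

    ``level="participant"`` returns one row per participant x condition.
    ``level="dyad"`` returns one row per dyad x condition, where the human
    dyad value is the mean of the two members' per-participant means and the
    avatar has one value per dyad.
    """
    if table.empty:
        raise IncompleteDesignError("empty metrics table")
    sub = table[table["actor"] == actor]
    if sub.empty:
        raise IncompleteDesignError(f"no rows for actor {actor!r}")
    metric_cols = [c for c in METRIC_NAMES if c in sub.columns]
    per_part = (
        sub.groupby(["dyad_id", "participant_id", "condition"], as_index=False)[metric_cols]
        .mean()
    )
    if level == "participant":
        return per_part
    if level != "dyad":
        raise InvalidArgumentError(f"unknown aggregation level {level!r}")
    return per_part.groupby(["dyad_id", "condition"], as_index=False)[metric_cols].mean()


def condition_pivot(agg: pd.DataFrame, metric: str, condition: str) -> np.ndarray:
    """Extract one metric for one condition as a unit-ordered vector."""
    sub = agg[agg["condition"] == condition].sort_values(agg.columns[0])
    if sub.empty:
        raise IncompleteDesignError(f"no rows for condition {condition!r}")
    return sub[metric].to_numpy()
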