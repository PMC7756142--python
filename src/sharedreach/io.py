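"""CSV/TSV dialects for trajectories, ratings, and result tables.

Trajectory CSV (one row per sample, header required, UTF-8, "." decimal):
``dyad_id, participant_id, actor, condition, session, trial, t_s, x_m, y_m,
z_m, target_x_m, target_y_m, target_z_m, target_edge_m, target_onset_s``.
Coordinates are right-handed meters, participant-facing +y forward (a
documented convention, not asserted).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import ParseError
from .simulate import RatingRecord, SimTrial
from .trajectory import TargetSpec, TrajectorySamples

TRAJECTORY_COLUMNS = [
    "dyad_id", "participant_id", "actor", "condition", "session", "trial",
    "t_s", "x_m", "y_m", "z_m",
    "target_x_m", "target_y_m", "target_z_m", "target_edge_m", "target_onset_s",
]
_NUMERIC = TRAJECTORY_COLUMNS[6:]
_FLOAT_FMT = "%.12g"

RATING_COLUMNS = ["participant_id", "dyad_id", "condition", "agency", "ownership"]


def write_trajectories(trials: Iterable[SimTrial], path: str | Path) -> None:
    frames = []
    for t in trials:
        n = t.trajectory.n_samples
        frames.append(
            pd.DataFrame(
                {
                    "dyad_id": t.dyad_id,
                    "participant_id": t.participant_id,
                    "actor": t.actor,
                    "condition": t.condition,
                    "session": t.session,
                    "trial": t.trial_index,
                    "t_s": t.trajectory.times,
                    "x_m": t.trajectory.positions[:, 0],
                    "y_m": t.trajectory.positions[:, 1],
                    "z_m": t.trajectory.positions[:, 2],
                    "target_x_m": t.target.position[0],
                    "target_y_m": t.target.position[1],
                    "target_z_m": t.target.position[2],
                    "target_edge_m": t.target.edge_length,
                    "target_onset_s": t.target.onset_time,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectories(path: str | Path) -> list[SimTrial]:
    """Parse and validate a trajectory CSV into raw trial records.

    Missing columns and non-numeric cells are reported with their names and
    1-based file line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing required columns: {', '.join(missing)}")
    bad_lines: list[int] = []
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()] if df[col].dtype == object else df.index[coerced.isna()]
        bad_lines.extend(int(i) + 2 for i in bad)  # +2: header + 1-based
        df[col] = coerced
    if df[_NUMERIC].isna().any().any():
        bad_lines.extend(int(i) + 2 for i in df.index[df[_NUMERIC].isna().any(axis=1)])
    if bad_lines:
        shown = sorted(set(bad_lines))[:20]
        raise ParseError(f"malformed numeric values at lines {shown}")

    trials: list[SimTrial] = []
    keys = ["dyad_id", "participant_id", "actor", "condition", "session", "trial"]
    for key, group in df.groupby(keys, sort=True):
        dyad_id, pid, actor, condition, session, trial = key
        group = group.sort_values("t_s")
        traj = TrajectorySamples(
            group["t_s"].to_numpy(), group[["x_m", "y_m", "z_m"]].to_numpy()
        )
        target = TargetSpec(
            position=group[["target_x_m", "target_y_m", "target_z_m"]].iloc[0].to_numpy(),
            edge_length=float(group["target_edge_m"].iloc[0]),
            onset_time=float(group["target_onset_s"].iloc[0]),
        )
        trials.append(
            SimTrial(
                dyad_id=int(dyad_id),
                participant_id=str(pid),
                actor=str(actor),
                condition=str(condition),
                session=int(session),
                trial_index=int(trial),
                trajectory=traj,
                target=target,
            )
        )
    return trials


def write_ratings(ratings: Iterable[RatingRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "dyad_id": r.dyad_id,
                "condition": r.condition,
                "agency": r.agency,
                "ownership": r.ownership,
            }
            for r in ratings
        ],
        columns=RATING_COLUMNS,
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_ratings(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in RATING_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing required columns: {', '.join(missing)}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
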