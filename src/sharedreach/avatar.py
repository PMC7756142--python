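"""The shared-avatar model: the avatar hand is the pointwise mean of the two
members' hand positions on a common time base.

Averaging is done on end-effector (hand) position in Cartesian space, with
equal weights by default (each member contributes 50% to the avatar).  A
weight parameter is exposed for extensions but the shared-control model under
study is the plain mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, InvalidArgumentError
from .trajectory import TargetSpec, TrajectorySamples

_GRID_TOL = 1e-9


def align_time_base(
    a: TrajectorySamples, b: TrajectorySamples
) -> tuple[TrajectorySamples, TrajectorySamples]:
    """Resample both trajectories onto one uniform grid covering the
    intersection of their time supports.

    The output grid keeps ``a``'s sampling phase and period; values are
    linearly interpolated, never extrapolated.
    """
    dt = a.dt
    if abs(b.dt - dt) > 1e-6 * dt:
        raise AlignmentError("sampling periods differ; resample first")
    if a.n_samples == b.n_samples and np.array_equal(a.times, b.times):
        return a, b
    t0 = max(a.times[0], b.times[0])
    t1 = min(a.times[-1], b.times[-1])
    if t1 - t0 < dt:
        raise AlignmentError("time supports overlap by fewer than 2 samples")
    # snap the window onto a's grid
    k0 = int(np.ceil((t0 - a.times[0]) / dt - 1e-9))
    k1 = int(np.floor((t1 - a.times[0]) / dt + 1e-9))
    grid = a.times[0] + np.arange(k0, k1 + 1) * dt
    if len(grid) < 2:
        raise AlignmentError("time supports overlap by fewer than 2 samples")
    return (
        TrajectorySamples(grid, a.at(grid)),
        TrajectorySamples(grid, b.at(grid)),
    )


def average_trajectories(
    a: TrajectorySamples, b: TrajectorySamples, weight_a: float = 0.5
) -> TrajectorySamples:
    """Weighted pointwise mean of two trajectories on the same grid.

    position(t) = weight_a * a(t) + (1 - weight_a) * b(t); times unchanged.
    """
    if not 0.0 <= weight_a <= 1.0:
        raise InvalidArgumentError("weight_a must lie in [0, 1]")
    if a.n_samples != b.n_samples or np.max(np.abs(a.times - b.times)) > _GRID_TOL:
        raise InvalidArgumentError(
            "trajectories are on different grids; call align_time_base first"
        )
    pos = weight_a * a.positions + (1.0 - weight_a) * b.positions
    return TrajectorySamples(a.times.copy(), pos)


def estimate_avatar_weight(
    avatar: TrajectorySamples, a: TrajectorySamples, b: TrajectorySamples
) -> float:
    """Least-squares estimate of member a's weight in the avatar.

    Solves min_w || avatar - (w a + (1-w) b) ||^2 over all samples and axes;
    equals 0.5 exactly when the avatar is the plain mean.
    """
    da = (a.positions - b.positions).ravel()
    dv = (avatar.positions - b.positions).ravel()
    denom = float(da @ da)
    if denom == 0.0:
        raise InvalidArgumentError("members are identical; weight unidentifiable")
    return float(dv @ da) / denom


@dataclass(frozen=True)
class DyadTrial:
    """One shared-condition trial: both members' raw trajectories and the
    avatar derived from them, all sharing one target."""

    member_a: TrajectorySamples
    member_b: TrajectorySamples
    avatar: TrajectorySamples
    target: TargetSpec

    @classmethod
    def from_members(
        cls, a: TrajectorySamples, b: TrajectorySamples, target: TargetSpec
    ) -> "DyadTrial":
        a2, b2 = align_time_base(a, b)
        return cls(a2, b2, average_trajectories(a2, b2), target)
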