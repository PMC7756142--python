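"""Uniformly sampled 3-D hand trajectories and the minimum-jerk reach model.

The minimum-jerk profile is the canonical normative model of point-to-point
human reaching: the hand path is straight and the time course follows the
quintic ``s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5`` with zero velocity and
acceleration at both endpoints.  It serves both as the noiseless base of the
synthetic generator and as a closed-form oracle for the kinematic metrics
(its speed and jerk profiles are polynomial in normalized time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError

#: tolerance on grid uniformity, seconds
_DT_TOL = 1e-9


@dataclass(frozen=True)
class TrajectorySamples:
    """A hand path sampled on a uniform time grid.

    Attributes
    ----------
    times : (n,) float array, seconds, strictly increasing, uniform spacing.
    positions : (n, 3) float array, meters.
    """

    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        if positions.ndim != 2 or positions.shape[1] != 3:
            raise InvalidArgumentError("positions must have shape (n, 3)")
        if times.ndim != 1 or len(times) != len(positions):
            raise InvalidArgumentError("times and positions must have equal length")
        if len(times) < 2:
            raise InvalidArgumentError("a trajectory needs at least 2 samples")
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise InvalidArgumentError("times must be strictly increasing")
        if np.max(np.abs(steps - np.median(steps))) >= _DT_TOL:
            raise InvalidArgumentError("time grid must be uniform")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(positions))):
            raise InvalidArgumentError("times and positions must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times)))

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def window(self, t0: float, t1: float) -> "TrajectorySamples":
        """Clip to samples with t0 <= t <= t1 (half-sample tolerance)."""
        eps = 0.5 * self.dt
        mask = (self.times >= t0 - eps) & (self.times <= t1 + eps)
        if mask.sum() < 2:
            raise InvalidArgumentError("window contains fewer than 2 samples")
        return TrajectorySamples(self.times[mask], self.positions[mask])

    def at(self, times: np.ndarray) -> np.ndarray:
        """Linear interpolation of position at arbitrary times (no extrapolation)."""
        times = np.asarray(times, dtype=float)
        if times.min() < self.times[0] - _DT_TOL or times.max() > self.times[-1] + _DT_TOL:
            raise InvalidArgumentError("requested times outside trajectory support")
        out = np.empty((len(times), 3))
        for k in range(3):
            out[:, k] = np.interp(times, self.times, self.positions[:, k])
        return out


@dataclass(frozen=True)
class TargetSpec:
    """A cube target: center position, edge length, and appearance time."""

    position: np.ndarray  # (3,), meters
    edge_length: float  # meters
    onset_time: float = 0.0  # seconds

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise InvalidArgumentError("target position must be a 3-vector")
        if self.edge_length <= 0:
            raise InvalidArgumentError("edge_length must be > 0")
        if self.onset_time < 0:
            raise InvalidArgumentError("onset_time must be >= 0")
        object.__setattr__(self, "position", pos)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: which points lie inside the axis-aligned cube."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        half = self.edge_length / 2.0
        return np.all(np.abs(points - self.position) <= half, axis=1)


# ---------------------------------------------------------------------------
# minimum-jerk closed forms (normalized time tau in [0, 1])

def min_jerk_s(tau: np.ndarray) -> np.ndarray:
    """Normalized displacement 10 tau^3 - 15 tau^4 + 6 tau^5."""
    tau = np.asarray(tau, dtype=float)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def min_jerk_speed(tau: np.ndarray) -> np.ndarray:
    """d s / d tau = 30 tau^2 - 60 tau^3 + 30 tau^4; peak 1.875 at tau = 1/2."""
    tau = np.asarray(tau, dtype=float)
    return 30.0 * tau**2 * (1.0 - tau) ** 2


def min_jerk_jerk(tau: np.ndarray) -> np.ndarray:
    """d^3 s / d tau^3 = 60 - 360 tau + 360 tau^2."""
    tau = np.asarray(tau, dtype=float)
    return 60.0 - 360.0 * tau + 360.0 * tau**2


#: normalized time at which the quintic speed first exceeds 10% of its peak
#: (solves 30 tau^2 (1-tau)^2 = 0.1 * 1.875)
MIN_JERK_RT_TAU = float((1.0 - np.sqrt(1.0 - 4.0 * np.sqrt(0.1 * 1.875 / 30.0))) / 2.0)


def min_jerk_traj(start, end, duration: float, dt: float) -> TrajectorySamples:
    """Point-to-point minimum-jerk reach sampled at period ``dt``.

    The path is the straight segment from ``start`` to ``end``; the time
    course is the quintic profile, so boundary velocity and acceleration
    vanish.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    if duration <= 0 or dt <= 0:
        raise InvalidArgumentError("duration and dt must be positive")
    if duration < 2 * dt:
        raise InvalidArgumentError("duration must be at least 2*dt")
    n = int(round(duration / dt)) + 1
    times = np.arange(n) * dt
    tau = times / duration
    pos = start[None, :] + min_jerk_s(tau)[:, None] * (end - start)[None, :]
    return TrajectorySamples(times, pos)
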