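"""Synthetic dyadic reaching experiments.

The generator emulates the statistical structure of a two-person
shared-avatar reaching study: dyads of participants reach to cube targets in
a frontal workspace under two conditions, *solo* (each person drives their
own avatar) and *shared* (the avatar hand is the mean of the two hands).
Sessions alternate between conditions in counter-balanced order across
dyads.

Each human reach is a straight minimum-jerk transport plus three deviation
terms:

* a *bow*: an idiosyncratic lateral curvature (direction fixed per
  participant, amplitude ``curvature_amp`` jittered per trial) with time
  profile sin^2(pi tau), so every solo reach has positive reach deviation;
* signal-dependent *motor noise*: a stationary Ornstein-Uhlenbeck process
  (time constant ``noise_smooth_tau``) scaled by the normalized base speed,
  so the hand is quiet at rest and at the endpoint and third derivatives
  exist numerically;
* in the shared condition, a cooperative *strategy*: the bow is scaled by
  (1 - strategy_gain) and the noise amplitude by (1 - strategy_gain/2)
  (partners straighten and steady their own commands to make the avatar
  path predictable), while an anti-correlated divergence term
  +/- divergence_amp * tau^2 pushes the two hands apart late in the reach
  and the endpoint aim scatter is multiplied by ``te_inflation``.

The divergence cancels in the avatar (the two members carry opposite
signs), so with strategy_gain = 1, divergence_amp = 0 and zero noise the
avatar reproduces the straight minimum-jerk path exactly.

Embodiment ratings are generated per participant and condition: agency on a
0-100% scale, ownership on a -3..+3 Likert scale, with monotone links that
make shared-condition ownership increase with the avatar's reach deviation
and the agency drop track the jerk change between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import kinematics
from .avatar import average_trajectories
from .errors import InvalidArgumentError, NoTouchError
from .trajectory import (
    MIN_JERK_RT_TAU,
    TargetSpec,
    TrajectorySamples,
    min_jerk_s,
    min_jerk_speed,
)

#: hand rest position (meters; +y forward, +z up)
START_POS = np.array([0.0, 0.25, 1.00])
#: frontal workspace box for target centers (min, max per axis)
WORKSPACE = (np.array([-0.25, 0.55, 0.85]), np.array([0.25, 0.75, 1.35]))
#: hold time after the slower member's planned movement end, seconds
TAIL_PAD = 0.10
#: per-participant spread of mean reaction time, seconds
RT_BETWEEN_SD = 0.02
#: fraction of trial-level RT variance shared by the dyad (stimulus-driven)
RT_SHARED_FRAC = 0.5
#: per-member jitter around the trial's common reach duration, seconds
DURATION_JITTER_SD = 0.02
#: population-level bow direction (right-handed reachers curve similarly);
#: per-participant directions scatter around it
BOW_POP_DIR = np.array([1.0, 0.0, 0.35])
BOW_DIR_SPREAD = 0.3


@dataclass(frozen=True)
class SimConfig:
    """Study-design and generative parameters of the synthetic experiment."""

    n_dyads: int = 10
    trials_per_session: int = 15
    n_sessions_per_condition: int = 4
    dt: float = 0.01  # s, sampling period
    reach_duration_range: tuple[float, float] = (0.5, 0.8)  # s
    rt_mean: float = 0.30  # s
    rt_sd: float = 0.05  # s, within-participant trial-to-trial spread
    curvature_amp: float = 0.015  # m, natural path bow amplitude
    noise_sd: float = 0.002  # m, motor-noise scale at peak speed
    noise_smooth_tau: float = 0.05  # s, noise low-pass time constant
    strategy_gain: float = 0.7  # in [0, 1]
    divergence_amp: float = 0.045  # m, late-phase anti-correlated divergence
    divergence_ramp_end: float = 0.75  # movement fraction at which divergence saturates
    te_inflation: float = 1.5  # >= 1, shared-condition endpoint-scatter multiplier
    rating_link_slope: float = 6.0  # agency % per SD of the linked metric
    rating_noise_sd: float = 10.0  # agency %, ownership uses 1/10 of this
    seed: int = 0
    # study constants (exposed for completeness)
    target_edge: float = 0.12  # m, cube side
    target_onset: float = 0.20  # s
    aim_sd: float = 0.008  # m, per-axis endpoint aim scatter (solo)
    agency_solo_mean: float = 85.0
    agency_shared_mean: float = 65.0
    ownership_solo_mean: float = 1.8
    ownership_shared_mean: float = 0.5

    def validate(self) -> None:
        if self.dt <= 0:
            raise InvalidArgumentError("dt must be > 0")
        if not 0.0 <= self.strategy_gain <= 1.0:
            raise InvalidArgumentError("strategy_gain must lie in [0, 1]")
        lo, hi = self.reach_duration_range
        if not 0 < lo <= hi:
            raise InvalidArgumentError("reach_duration_range must satisfy 0 < min <= max")
        for name in ("rt_sd", "curvature_amp", "noise_sd", "divergence_amp",
                     "rating_noise_sd", "aim_sd"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if self.te_inflation < 1.0:
            raise InvalidArgumentError("te_inflation must be >= 1")
        if self.noise_smooth_tau <= 0:
            raise InvalidArgumentError("noise_smooth_tau must be > 0")
        if min(self.n_dyads, self.trials_per_session, self.n_sessions_per_condition) < 1:
            raise InvalidArgumentError("counts must be >= 1")


@dataclass(frozen=True)
class RatingRecord:
    participant_id: str
    dyad_id: int
    condition: str
    agency: float  # percent in [0, 100]
    ownership: int  # integer in [-3, +3]

    def __post_init__(self) -> None:
        if not 0.0 <= self.agency <= 100.0:
            raise InvalidArgumentError("agency must lie in [0, 100]")
        if not -3 <= int(self.ownership) <= 3:
            raise InvalidArgumentError("ownership must lie in [-3, 3]")


@dataclass(frozen=True)
class SimTrial:
    """One raw (unsegmented) recording, plus generator ground truth."""

    dyad_id: int
    participant_id: str
    actor: str  # "human" | "avatar"
    condition: str
    session: int  # 1..n within condition
    trial_index: int
    trajectory: TrajectorySamples
    target: TargetSpec
    truth: dict = field(default_factory=dict)


@dataclass(frozen=True)
class MemberStrategy:
    """Per-member deterministic deviation directions for one trial."""

    bow_dir: np.ndarray  # unit vector, lateral bow direction
    bow_amp: float  # m, jittered amplitude for this trial
    divergence_dir: np.ndarray  # unit vector shared by the dyad
    divergence_sign: float  # +1 for one member, -1 for the other


def divergence_weight(tau: np.ndarray, ramp_end: float) -> np.ndarray:
    """Divergence time profile: a smoothstep rise saturating at
    ``ramp_end`` of movement time.

    Monotone non-decreasing in tau and C1 everywhere, so the hands diverge
    most in the later movement phases while the drift velocity stays
    continuous and the endpoint offset equals the full amplitude.
    """
    x = np.clip(np.asarray(tau, dtype=float) / ramp_end, 0.0, 1.0)
    return x**2 * (3.0 - 2.0 * x)


def _perp_component(v: np.ndarray, chord: np.ndarray) -> np.ndarray:
    """Unit component of v perpendicular to the chord direction."""
    c = chord / np.linalg.norm(chord)
    perp = v - (v @ c) * c
    norm = np.linalg.norm(perp)
    if norm < 1e-9:  # v (nearly) parallel to the reach: pick any lateral axis
        basis = np.eye(3)
        k = int(np.argmin(np.abs(c)))
        perp = basis[k] - (basis[k] @ c) * c
        norm = np.linalg.norm(perp)
    return perp / norm


def apply_strategy(
    base: TrajectorySamples,
    tau: np.ndarray,
    condition: str,
    cfg: SimConfig,
    strategy: MemberStrategy,
    unit_noise: np.ndarray,
) -> TrajectorySamples:
    """Add one member's deviations (bow, divergence, motor noise) to the
    straight minimum-jerk base.

    ``tau`` is the movement phase per sample (0 before onset, 1 after the
    planned end); ``unit_noise`` is a unit-variance smooth noise process of
    the same length, scaled here by the condition's noise amplitude and the
    normalized base speed.
    """
    if condition not in ("solo", "shared"):
        raise InvalidArgumentError(f"unknown condition {condition!r}")
    chord = base.positions[-1] - base.positions[0]
    if np.linalg.norm(chord) == 0.0:
        chord = np.array([0.0, 1.0, 0.0])
    bow_u = _perp_component(strategy.bow_dir, chord)
    shared = condition == "shared"
    bow_scale = (1.0 - cfg.strategy_gain) if shared else 1.0
    noise_scale = cfg.noise_sd * ((1.0 - cfg.strategy_gain / 2.0) if shared else 1.0)

    moving = (tau > 0.0) & (tau < 1.0)
    bow_w = np.where(moving, np.sin(np.pi * tau) ** 2, 0.0)
    dev = (strategy.bow_amp * bow_scale) * bow_w[:, None] * bow_u[None, :]
    if shared and cfg.divergence_amp > 0.0:
        div_u = _perp_component(strategy.divergence_dir, chord)
        w = divergence_weight(tau, cfg.divergence_ramp_end)
        dev = dev + (
            strategy.divergence_sign * cfg.divergence_amp
        ) * w[:, None] * div_u[None, :]
    envelope = min_jerk_speed(np.clip(tau, 0.0, 1.0)) / 1.875
    dev = dev + noise_scale * envelope[:, None] * unit_noise
    return TrajectorySamples(base.times, base.positions + dev)


@lru_cache(maxsize=32)
def _smooth_noise_gain(dt: float, tau_c: float) -> float:
    """Stationary sd of white noise passed through the 3-pole low-pass."""
    rho = float(np.exp(-dt / tau_c))
    n_imp = max(64, int(20.0 * tau_c / dt))
    impulse = np.zeros(n_imp)
    impulse[0] = 1.0
    h = impulse
    for _ in range(3):
        h = lfilter([1.0 - rho], [1.0, -rho], h)
    return float(np.sqrt(np.sum(h**2)))


def _smooth_noise(n: int, dt: float, tau_c: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance smooth motor noise, (n, 3).

    White noise through three cascaded first-order low-passes with time
    constant ``tau_c``, so the numerical third derivative is finite (a
    single pole would leave jerk dominated by the sampling period).  A
    burn-in of 6 time constants removes the filter transient.
    """
    rho = float(np.exp(-dt / tau_c))
    burn = int(6.0 * tau_c / dt)
    x = rng.standard_normal((n + burn, 3))
    for _ in range(3):
        x = lfilter([1.0 - rho], [1.0, -rho], x, axis=0)
    return x[burn:] / _smooth_noise_gain(dt, tau_c)


def _member_trajectory(
    cfg: SimConfig,
    grid: np.ndarray,
    target: TargetSpec,
    aim: np.ndarray,
    rt: float,
    duration: float,
    condition: str,
    strategy: MemberStrategy,
    rng: np.random.Generator,
) -> tuple[TrajectorySamples, dict]:
    move_onset = target.onset_time + rt
    tau = np.clip((grid - move_onset) / duration, 0.0, 1.0)
    base_pos = START_POS[None, :] + min_jerk_s(tau)[:, None] * (aim - START_POS)[None, :]
    base = TrajectorySamples(grid, base_pos)
    noise = _smooth_noise(len(grid), cfg.dt, cfg.noise_smooth_tau, rng)
    traj = apply_strategy(base, tau, condition, cfg, strategy, noise)
    inside = target.contains(traj.positions) & (grid >= target.onset_time)
    touch_true = float(grid[int(np.argmax(inside))]) if inside.any() else None
    truth = {
        "rt_draw": rt,
        "move_onset": move_onset,
        "rt_threshold_time": rt + MIN_JERK_RT_TAU * duration,
        "duration": duration,
        "touch_time": touch_true,
        "aim": aim,
    }
    return traj, truth


def _session_order(dyad_id: int, n_per_condition: int) -> list[tuple[str, int]]:
    """Alternating conditions, half the dyads starting with solo."""
    first, second = ("solo", "shared") if dyad_id % 2 == 0 else ("shared", "solo")
    order = []
    for s in range(1, n_per_condition + 1):
        order.append((first, s))
        order.append((second, s))
    return order


def generate_dyad_experiment(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[SimTrial], list[RatingRecord]]:
    """Generate every raw reach record and the embodiment ratings.

    Returns ``n_dyads * 2 members * 2 conditions * sessions * trials`` human
    records plus one avatar record per shared trial, fully deterministic
    under ``cfg.seed``.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    trials: list[SimTrial] = []
    lo, hi = WORKSPACE
    for dyad in range(cfg.n_dyads):
        member_ids = [f"p{2 * dyad:02d}", f"p{2 * dyad + 1:02d}"]
        rt_means = cfg.rt_mean + RT_BETWEEN_SD * rng.standard_normal(2)
        bow_dirs = BOW_POP_DIR[None, :] + BOW_DIR_SPREAD * rng.standard_normal((2, 3))
        bow_dirs /= np.linalg.norm(bow_dirs, axis=1, keepdims=True)
        div_dir = rng.standard_normal(3)
        div_dir /= np.linalg.norm(div_dir)
        for condition, session in _session_order(dyad, cfg.n_sessions_per_condition):
            for k in range(cfg.trials_per_session):
                target = TargetSpec(
                    position=rng.uniform(lo, hi),
                    edge_length=cfg.target_edge,
                    onset_time=cfg.target_onset,
                )
                # trial-level RT: a component shared by the dyad (stimulus
                # salience) plus an individual component
                rt_common = np.sqrt(RT_SHARED_FRAC) * cfg.rt_sd * rng.standard_normal()
                rt_indiv = np.sqrt(1.0 - RT_SHARED_FRAC) * cfg.rt_sd * rng.standard_normal(2)
                rts = np.maximum(0.10, rt_means + rt_common + rt_indiv)
                # both members reach to the same target: one common duration
                # draw plus a small per-member jitter
                dur_common = rng.uniform(*cfg.reach_duration_range)
                durs = np.clip(
                    dur_common + DURATION_JITTER_SD * rng.standard_normal(2),
                    *cfg.reach_duration_range,
                )
                aim_sd = cfg.aim_sd * (cfg.te_inflation if condition == "shared" else 1.0)
                aims = target.position[None, :] + aim_sd * rng.standard_normal((2, 3))
                t_end = target.onset_time + float(np.max(rts + durs)) + TAIL_PAD
                grid = np.arange(int(round(t_end / cfg.dt)) + 1) * cfg.dt
                member_trajs = []
                for m in range(2):
                    strategy = MemberStrategy(
                        bow_dir=bow_dirs[m],
                        bow_amp=cfg.curvature_amp * max(0.0, 1.0 + 0.3 * rng.standard_normal()),
                        divergence_dir=div_dir,
                        divergence_sign=1.0 if m == 0 else -1.0,
                    )
                    traj, truth = _member_trajectory(
                        cfg, grid, target, aims[m], float(rts[m]), float(durs[m]),
                        condition, strategy, rng,
                    )
                    member_trajs.append(traj)
                    trials.append(
                        SimTrial(
                            dyad_id=dyad,
                            participant_id=member_ids[m],
                            actor="human",
                            condition=condition,
                            session=session,
                            trial_index=k,
                            trajectory=traj,
                            target=target,
                            truth=truth,
                        )
                    )
                if condition == "shared":
                    av = average_trajectories(*member_trajs)
                    inside = target.contains(av.positions) & (grid >= target.onset_time)
                    touch_true = float(grid[int(np.argmax(inside))]) if inside.any() else None
                    trials.append(
                        SimTrial(
                            dyad_id=dyad,
                            participant_id=kinematics.AVATAR_ID,
                            actor="avatar",
                            condition=condition,
                            session=session,
                            trial_index=k,
                            trajectory=av,
                            target=target,
                            truth={"touch_time": touch_true},
                        )
                    )
    ratings = generate_ratings(_rating_summaries(cfg, trials), cfg, rng)
    return trials, ratings


def segment_experiment(
    trials: Iterable[SimTrial],
) -> tuple[list[kinematics.ReachTrial], int]:
    """Segment every raw record by the touch rule.

    Returns the segmented trials and the count of excluded (no-touch)
    records.
    """
    out: list[kinematics.ReachTrial] = []
    excluded = 0
    for t in trials:
        try:
            out.append(
                kinematics.segment_reach(
                    t.trajectory,
                    t.target,
                    dyad_id=t.dyad_id,
                    participant_id=t.participant_id,
                    condition=t.condition,
                    session=t.session,
                    trial_index=t.trial_index,
                )
            )
        except NoTouchError:
            excluded += 1
    return out, excluded


def _rating_summaries(cfg: SimConfig, trials: list[SimTrial]) -> pd.DataFrame:
    """Per-participant metric summary used by the rating links.

    One row per participant x condition, with the participant's mean jerk
    ``J`` and (for shared rows) the dyad's avatar reach deviation
    ``D_avatar``.
    """
    segmented, _ = segment_experiment(trials)
    table = kinematics.metrics_table(segmented)
    human = kinematics.aggregate_metrics(table, level="participant", actor="human")
    avatar = kinematics.aggregate_metrics(table, level="dyad", actor="avatar")
    av_d = avatar.set_index("dyad_id")["D"]
    human = human.copy()
    human["D_avatar"] = np.where(
        human["condition"] == "shared",
        human["dyad_id"].map(av_d),
        np.nan,
    )
    return human[["participant_id", "dyad_id", "condition", "D", "J", "D_avatar"]]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_ratings(
    summary: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator
) -> list[RatingRecord]:
    """Draw agency and ownership ratings linked to the kinematic summary.

    Shared-condition ownership increases with the avatar's reach deviation;
    shared-condition agency decreases with the participant's jerk change
    (shared minus solo), so the agency drop correlates with the jerk change.
    """
    required = {"participant_id", "dyad_id", "condition", "J"}
    if not required.issubset(summary.columns):
        raise InvalidArgumentError(f"summary must contain columns {sorted(required)}")
    wide = summary.pivot(index="participant_id", columns="condition", values="J")
    if "solo" not in wide.columns or "shared" not in wide.columns or wide.isna().any().any():
        raise InvalidArgumentError("every participant needs both conditions")
    participants = list(wide.index)
    dyads = summary.drop_duplicates("participant_id").set_index("participant_id")["dyad_id"]
    delta_j = _zscore((wide["shared"] - wide["solo"]).to_numpy())
    if "D_avatar" in summary.columns:
        d_av = (
            summary[summary["condition"] == "shared"]
            .set_index("participant_id")["D_avatar"]
            .reindex(participants)
            .to_numpy()
        )
        d_av = _zscore(np.nan_to_num(d_av, nan=0.0))
    else:
        d_av = np.zeros(len(participants))

    slope = cfg.rating_link_slope
    own_noise = cfg.rating_noise_sd / 10.0
    records: list[RatingRecord] = []
    for i, pid in enumerate(participants):
        agency_solo = float(
            np.clip(rng.normal(cfg.agency_solo_mean, cfg.rating_noise_sd), 0.0, 100.0)
        )
        agency_shared = float(
            np.clip(
                cfg.agency_shared_mean
                - slope * delta_j[i]
                + rng.normal(0.0, cfg.rating_noise_sd),
                0.0,
                100.0,
            )
        )
        own_solo = int(np.clip(round(rng.normal(cfg.ownership_solo_mean, own_noise)), -3, 3))
        own_shared = int(
            np.clip(
                round(
                    cfg.ownership_shared_mean
                    + (slope / 10.0) * d_av[i]
                    + rng.normal(0.0, own_noise)
                ),
                -3,
                3,
            )
        )
        dyad = int(dyads[pid])
        records.append(RatingRecord(pid, dyad, "solo", agency_solo, own_solo))
        records.append(RatingRecord(pid, dyad, "shared", agency_shared, own_shared))
    return records


def averaging_null_config(cfg: SimConfig | None = None, **overrides) -> SimConfig:
    """The averaging-only null: no cooperative strategy, no divergence, no
    shared-condition endpoint inflation — shared behavior is statistically
    identical to solo, and any avatar improvement is pure noise averaging."""
    base = cfg or SimConfig()
    return replace(
        base, strategy_gain=0.0, divergence_amp=0.0, te_inflation=1.0, **overrides
    )
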