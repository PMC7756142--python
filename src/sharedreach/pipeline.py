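"""End-to-end orchestration: simulate (or load) -> segment -> avatar ->
metrics -> interpersonal distance -> statistical battery -> report.

Runs are deterministic under a fixed seed; the emitted manifest records the
configuration hash, seed, package version, and excluded-trial counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .avatar import average_trajectories
from .battery import BatteryReport, battery_frame, run_test_battery
from .errors import InvalidArgumentError, NoDataError
from .io import read_ratings, read_trajectories, write_ratings, write_trajectories, write_tsv
from .kinematics import ReachTrial, interpersonal_distance, metrics_table
from .simulate import SimConfig, SimTrial, generate_dyad_experiment, segment_experiment

log = logging.getLogger("sharedreach")


@dataclass(frozen=True)
class RunConfig:
    """One reproducible pipeline run."""

    mode: str = "simulate"  # "simulate" | "analyze"
    sim: SimConfig = field(default_factory=SimConfig)
    trajectories_path: str | None = None  # analyze mode input
    ratings_path: str | None = None
    out_dir: str = "results"
    ip_window: str = "later_touch"  # | "earlier_touch"
    alpha: float = 0.05
    d_convention: str = "dz"
    seed: int | None = None  # overrides sim.seed when set
    write_trajectory_csv: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise InvalidArgumentError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.alpha < 1.0:
            raise InvalidArgumentError("alpha must lie in (0, 1)")
        if self.mode == "analyze" and not self.trajectories_path:
            raise InvalidArgumentError("analyze mode needs trajectories_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)

    def effective_sim(self) -> SimConfig:
        if self.seed is not None:
            return dataclasses.replace(self.sim, seed=self.seed)
        return self.sim


@dataclass
class PipelineResult:
    config: RunConfig
    metrics: pd.DataFrame  # per-trial metric table (humans + avatar)
    ip: pd.DataFrame  # per-paired-trial IP table
    report: BatteryReport
    ratings: pd.DataFrame | None
    n_trials: int
    n_excluded: int
    manifest: dict


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_avatars(raw: list[SimTrial]) -> list[SimTrial]:
    """Add avatar records (mean of the two members) to shared trials that
    lack them, e.g. when loading member-only CSV data."""
    have = {
        (t.dyad_id, t.condition, t.session, t.trial_index)
        for t in raw
        if t.actor == "avatar"
    }
    by_trial: dict[tuple, list[SimTrial]] = {}
    for t in raw:
        if t.actor == "human" and t.condition == "shared":
            by_trial.setdefault((t.dyad_id, t.condition, t.session, t.trial_index), []).append(t)
    out = list(raw)
    for key, members in sorted(by_trial.items()):
        if key in have or len(members) != 2:
            continue
        a, b = sorted(members, key=lambda t: t.participant_id)
        out.append(
            SimTrial(
                dyad_id=a.dyad_id,
                participant_id="avatar",
                actor="avatar",
                condition=a.condition,
                session=a.session,
                trial_index=a.trial_index,
                trajectory=average_trajectories(a.trajectory, b.trajectory),
                target=a.target,
            )
        )
    return out


def ip_table(segmented: list[ReachTrial], window: str = "later_touch") -> pd.DataFrame:
    """Per-trial inter-participant distance for every dyad trial with both
    members present (computed in both conditions)."""
    by_trial: dict[tuple, list[ReachTrial]] = {}
    for t in segmented:
        if t.actor == "human":
            by_trial.setdefault(
                (t.dyad_id, t.condition, t.session, t.trial_index), []
            ).append(t)
    rows = []
    for (dyad, condition, session, trial), members in sorted(by_trial.items()):
        if len(members) != 2:
            continue  # partner trial excluded (no touch)
        res = interpersonal_distance(members[0], members[1], window=window)
        rows.append(
            {
                "dyad_id": dyad,
                "condition": condition,
                "session": session,
                "trial": trial,
                "overall": res.overall,
                "phase1": res.phases[0],
                "phase2": res.phases[1],
                "phase3": res.phases[2],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["dyad_id", "condition", "session", "trial",
                 "overall", "phase1", "phase2", "phase3"],
    )


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full pipeline and write the artifact bundle.

    Artifacts: ``metrics.tsv``, ``ip.tsv``, ``stats_report.tsv``,
    ``stats_report.txt``, ``manifest.json`` (plus the simulated trajectory
    and ratings CSVs when requested).
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.mode == "simulate":
        sim_cfg = cfg.effective_sim()
        log.info("[simulate] generating %d dyads", sim_cfg.n_dyads)
        raw, rating_records = generate_dyad_experiment(sim_cfg)
        ratings = pd.DataFrame(
            [dataclasses.asdict(r) for r in rating_records]
        )
        if cfg.write_trajectory_csv:
            write_trajectories(raw, out / "trajectories.csv")
            write_ratings(rating_records, out / "ratings.csv")
    else:
        log.info("[load] reading %s", cfg.trajectories_path)
        raw = read_trajectories(cfg.trajectories_path)
        ratings = read_ratings(cfg.ratings_path) if cfg.ratings_path else None

    if not raw:
        raise NoDataError("no trials to analyze")
    raw = build_avatars(raw)

    log.info("[segment] %d raw records", len(raw))
    segmented, excluded = segment_experiment(raw)
    if not segmented:
        raise NoDataError("every trial was excluded by the touch rule")
    if excluded:
        log.warning("[segment] excluded %d no-touch trials", excluded)

    log.info("[metrics] computing per-trial statistics")
    metrics = metrics_table(segmented)
    ip = ip_table(segmented, window=cfg.ip_window)

    log.info("[stats] running the test battery")
    report = run_test_battery(
        metrics, ip, ratings, alpha=cfg.alpha, d_convention=cfg.d_convention
    )

    manifest = {
        "package": "sharedreach",
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg.effective_sim().seed if cfg.mode == "simulate" else None,
        "mode": cfg.mode,
        "n_raw_records": len(raw),
        "n_segmented": len(segmented),
        "n_excluded_no_touch": excluded,
    }

    write_tsv(metrics, out / "metrics.tsv")
    write_tsv(ip, out / "ip.tsv")
    frame = battery_frame(report)
    write_tsv(frame, out / "stats_report.tsv")
    with open(out / "stats_report.txt", "w") as fh:
        for name, entry in report.items():
            fh.write(f"{name} [{entry.branch}]: {entry.result}\n")
            for k, r in entry.extra_results.items():
                fh.write(f"  {k}: {r}\n")
            if entry.posthoc:
                for c in entry.posthoc.contrasts:
                    fh.write(
                        f"  {c.label}: t({c.df:g}) = {c.statistic:.3f}, "
                        f"adj.p = {c.p_adjusted:.4g}, d = {c.effect_size:.3f} "
                        f"({entry.posthoc.adjustment_method})\n"
                    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return PipelineResult(
        config=cfg,
        metrics=metrics,
        ip=ip,
        report=report,
        ratings=ratings,
        n_trials=len(segmented),
        n_excluded=excluded,
        manifest=manifest,
    )


def qualitative_pattern(result: PipelineResult) -> dict[str, bool]:
    """The sign pattern the cooperative regime is expected to reproduce.

    Orderings are evaluated on dyad-level grand means; IP late-phase
    concentration compares the shared-minus-solo gap across phases.
    """
    from .kinematics import aggregate_metrics

    human = aggregate_metrics(result.metrics, level="dyad", actor="human")
    avatar = aggregate_metrics(result.metrics, level="dyad", actor="avatar")

    def mean(df: pd.DataFrame, condition: str, metric: str) -> float:
        return float(df[df["condition"] == condition][metric].mean())

    d_solo, d_shared = mean(human, "solo", "D"), mean(human, "shared", "D")
    d_av = mean(avatar, "shared", "D")
    j_solo, j_shared = mean(human, "solo", "J"), mean(human, "shared", "J")
    j_av = mean(avatar, "shared", "J")
    te_solo, te_shared = mean(human, "solo", "TE"), mean(human, "shared", "TE")
    te_av = mean(avatar, "shared", "TE")
    rt_solo, rt_av = mean(human, "solo", "RT"), mean(avatar, "shared", "RT")

    per_dyad = result.ip.groupby(["dyad_id", "condition"])[
        ["overall", "phase1", "phase2", "phase3"]
    ].mean()
    ip_means = per_dyad.groupby("condition").mean()
    gap = ip_means.loc["shared"] - ip_means.loc["solo"]

    pattern = {
        "d_ordering": d_av < d_shared < d_solo,
        "j_ordering": j_av < j_shared < j_solo,
        "rt_avatar_faster": rt_av < rt_solo,
        "te_shared_human_largest": te_shared > max(te_solo, te_av),
        "ip_shared_greater": float(gap["overall"]) > 0.0,
        "ip_late_concentration": (
            float(gap["phase2"]) > float(gap["phase1"])
            and float(gap["phase3"]) > float(gap["phase1"])
        ),
    }
    if result.ratings is not None and len(result.ratings):
        shared_agency = result.ratings[result.ratings["condition"] == "shared"]["agency"]
        pattern["agency_shared_above_50"] = float(shared_agency.mean()) > 50.0
    pattern["all"] = all(pattern.values())
    return pattern
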