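"""Summary figures: condition means with standard-error bars and the
rating-kinematics scatter plots (SE = sd/sqrt(n) over the analysis unit)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import NoDataError
from .kinematics import aggregate_metrics
from .pipeline import PipelineResult


def _bar(ax, labels, values_per_level, title, ylabel):
    means = [np.mean(v) for v in values_per_level]
    ses = [np.std(v, ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0 for v in values_per_level]
    ax.bar(range(len(labels)), means, yerr=ses, capsize=4, color="0.7", edgecolor="0.2")
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=20, ha="right", fontsize=8)
    ax.set_title(title, fontsize=9)
    ax.set_ylabel(ylabel, fontsize=8)


def make_figures(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Write one PNG per analysis family; returns the file paths."""
    if result.metrics.empty:
        raise NoDataError("empty metrics table")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    human = aggregate_metrics(result.metrics, level="dyad", actor="human")
    avatar = aggregate_metrics(result.metrics, level="dyad", actor="avatar")

    def v(df: pd.DataFrame, cond: str, metric: str) -> np.ndarray:
        return df[df["condition"] == cond][metric].to_numpy()

    labels3 = ["solo human", "shared human", "shared avatar"]

    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    for ax, metric, unit in zip(axes, ("D", "J", "TE"), ("m", "m s$^{-3}$", "m")):
        _bar(ax, labels3,
             [v(human, "solo", metric), v(human, "shared", metric), v(avatar, "shared", metric)],
             f"{metric} per dyad", unit)
    fig.tight_layout()
    p = out / "kinematics.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, axes = plt.subplots(1, 2, figsize=(6, 3))
    _bar(axes[0], ["solo human", "shared avatar"],
         [v(human, "solo", "TT"), v(avatar, "shared", "TT")], "task time", "s")
    _bar(axes[1], ["solo human", "shared avatar"],
         [v(human, "solo", "RT"), v(avatar, "shared", "RT")], "reaction time", "s")
    fig.tight_layout()
    p = out / "performance.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    if not result.ip.empty:
        per_dyad = result.ip.groupby(["dyad_id", "condition"], as_index=False)[
            ["overall", "phase1", "phase2", "phase3"]
        ].mean()
        fig, axes = plt.subplots(1, 4, figsize=(10, 3))
        for ax, col in zip(axes, ("overall", "phase1", "phase2", "phase3")):
            _bar(ax, ["solo", "shared"],
                 [per_dyad[per_dyad["condition"] == c][col].to_numpy() for c in ("solo", "shared")],
                 f"IP {col}", "m")
        fig.tight_layout()
        p = out / "interpersonal_distance.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)

    if result.ratings is not None and len(result.ratings):
        r = result.ratings
        fig, axes = plt.subplots(1, 2, figsize=(6, 3))
        for ax, col, ylab in zip(axes, ("agency", "ownership"), ("%", "Likert")):
            _bar(ax, ["solo", "shared"],
                 [r[r["condition"] == c][col].to_numpy(dtype=float) for c in ("solo", "shared")],
                 f"sense of {col}", ylab)
        fig.tight_layout()
        p = out / "ratings.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)

        part = aggregate_metrics(result.metrics, level="participant", actor="human")
        av_d = avatar[avatar["condition"] == "shared"].set_index("dyad_id")["D"]
        wide_o = r.pivot(index="participant_id", columns="condition", values="ownership")
        wide_a = r.pivot(index="participant_id", columns="condition", values="agency")
        pj = part.pivot(index="participant_id", columns="condition", values="J")
        dyad_of = part.drop_duplicates("participant_id").set_index("participant_id")["dyad_id"]
        idx = wide_o.index
        fig, axes = plt.subplots(1, 2, figsize=(7, 3))
        axes[0].scatter(dyad_of.reindex(idx).map(av_d), wide_o["shared"], s=14, color="0.3")
        axes[0].set_xlabel("avatar reach deviation D (m)", fontsize=8)
        axes[0].set_ylabel("ownership (shared)", fontsize=8)
        axes[1].scatter((pj["shared"] - pj["solo"]).reindex(idx),
                        (wide_a["shared"] - wide_a["solo"]).reindex(idx), s=14, color="0.3")
        axes[1].set_xlabel("jerk change (m s$^{-3}$)", fontsize=8)
        axes[1].set_ylabel("agency change (%)", fontsize=8)
        fig.tight_layout()
        p = out / "rating_correlations.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)

    return paths
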