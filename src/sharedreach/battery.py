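"""The full analysis battery applied to one experiment's summaries.

Every analysis is gated by Shapiro–Wilk normality at ``alpha``: normal data
take the parametric branch (paired t / repeated-measures ANOVA with Holm
post hocs / Pearson), non-normal data the rank branch (Wilcoxon signed-rank
/ ART ANOVA with Tukey post hocs on aligned ranks / Spearman).  Kinematic
analyses run at the dyad level, rating analyses at the participant level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as st
from .errors import DegenerateSampleError, IncompleteDesignError, InvalidArgumentError
from .kinematics import aggregate_metrics


@dataclass(frozen=True)
class BatteryEntry:
    name: str
    branch: str  # "parametric" | "rank"
    gates: tuple[st.StatResult, ...]
    result: st.StatResult
    posthoc: st.PostHocTable | None = None
    extra_results: dict = field(default_factory=dict)


BatteryReport = dict[str, BatteryEntry]


def _gate_normal(samples: list[np.ndarray], alpha: float) -> tuple[bool, tuple[st.StatResult, ...]]:
    """Shapiro-Wilk gate; samples too small or constant to assess are
    skipped (the branch then defaults to parametric)."""
    gates = []
    normal = True
    for s in samples:
        try:
            g = st.shapiro_wilk(s)
        except (InvalidArgumentError, DegenerateSampleError):
            continue
        gates.append(g)
        normal = normal and g.p >= alpha
    return normal, tuple(gates)


def _paired_contrast(
    name: str, x: np.ndarray, y=None, mu=None, alpha: float = 0.05, d_convention: str = "dz"
) -> BatteryEntry:
    diffs = x - (y if y is not None else mu)
    normal, gates = _gate_normal([diffs], alpha)
    if normal:
        res = st.paired_t(x, y, mu=mu if mu is not None else 0.0, d_convention=d_convention)
        branch = "parametric"
    else:
        res = st.wilcoxon_signed_rank(x, y, mu=mu)
        branch = "rank"
    return BatteryEntry(name, branch, gates, res)


def _three_level_anova(
    name: str,
    table: np.ndarray,
    labels: tuple[str, ...],
    alpha: float,
) -> BatteryEntry:
    """Gate, omnibus, and post hocs for a one-way k-level within design."""
    normal, gates = _gate_normal([table[:, j] for j in range(table.shape[1])], alpha)
    try:
        sphericity = st.mauchly_sphericity(table)
        gates = gates + (sphericity,)
        spherical = sphericity.p >= alpha
    except (InvalidArgumentError, DegenerateSampleError):
        spherical = True  # not assessable on this design; gate on normality
    if normal and spherical:
        res = st.rm_anova_oneway(table)
        post = st.holm_posthoc(table, labels)
        branch = "parametric"
    else:
        res = st.art_rm_anova(table)["A"]
        post = st.tukey_posthoc(res.extras["aligned_ranks"], labels)
        res = st.StatResult(  # drop the bulky aligned ranks from the report
            res.test_name, res.statistic, res.df, res.p, res.effect_size,
            res.effect_size_type,
        )
        branch = "rank"
    return BatteryEntry(name, branch, gates, res, post)


def _dyad_vectors(metrics: pd.DataFrame) -> dict[str, np.ndarray]:
    """Dyad-ordered per-condition metric vectors for humans and the avatar."""
    human = aggregate_metrics(metrics, level="dyad", actor="human")
    avatar = aggregate_metrics(metrics, level="dyad", actor="avatar")
    dyads = sorted(human["dyad_id"].unique())
    out: dict[str, np.ndarray] = {}

    def vec(df: pd.DataFrame, condition: str, metric: str) -> np.ndarray:
        sub = df[df["condition"] == condition].set_index("dyad_id")[metric]
        if not set(dyads).issubset(sub.index):
            raise IncompleteDesignError(f"missing dyads for {metric}/{condition}")
        return sub.reindex(dyads).to_numpy()

    for m in ("D", "J", "RT", "TT", "TE"):
        out[f"{m}_solo_human"] = vec(human, "solo", m)
        out[f"{m}_shared_human"] = vec(human, "shared", m)
        out[f"{m}_shared_avatar"] = vec(avatar, "shared", m)
    return out


def _correlation(name: str, x: np.ndarray, y: np.ndarray, alpha: float) -> BatteryEntry:
    normal, gates = _gate_normal([x, y], alpha)
    if normal:
        r, p = sps.pearsonr(x, y)
        res = st.StatResult("pearson_r", float(r), (float(len(x)),), float(p), float(r), "pearson_r")
        branch = "parametric"
    else:
        res = st.spearman(x, y)
        branch = "rank"
    return BatteryEntry(name, branch, gates, res)


def run_test_battery(
    metrics: pd.DataFrame,
    ip: pd.DataFrame,
    ratings: pd.DataFrame | None = None,
    alpha: float = 0.05,
    d_convention: str = "dz",
) -> BatteryReport:
    """Run every analysis on the trial-level metrics, IP, and rating tables.

    ``metrics`` is the tidy per-trial table (humans and avatar); ``ip`` has
    one row per paired trial with columns overall/phase1..3/condition/
    session/dyad_id; ``ratings`` has one row per participant x condition
    with agency and ownership.
    """
    report: BatteryReport = {}
    v = _dyad_vectors(metrics)

    # --- reach deviation and jerk: three within-dyad cases -----------------
    labels = ("solo_human", "shared_human", "shared_avatar")
    for metric, name in (("D", "deviation_rm_anova"), ("J", "jerk_rm_anova"),
                         ("TE", "target_error_rm_anova")):
        table = np.column_stack(
            [v[f"{metric}_solo_human"], v[f"{metric}_shared_human"], v[f"{metric}_shared_avatar"]]
        )
        report[name] = _three_level_anova(name, table, labels, alpha)

    # --- task performance contrasts ----------------------------------------
    report["task_time_solo_vs_avatar"] = _paired_contrast(
        "task_time_solo_vs_avatar", v["TT_solo_human"], v["TT_shared_avatar"],
        alpha=alpha, d_convention=d_convention,
    )
    report["reaction_time_solo_vs_avatar"] = _paired_contrast(
        "reaction_time_solo_vs_avatar", v["RT_solo_human"], v["RT_shared_avatar"],
        alpha=alpha, d_convention=d_convention,
    )

    # --- inter-participant distance ----------------------------------------
    if not ip.empty:
        per_dyad = ip.groupby(["dyad_id", "condition"], as_index=False)[
            ["overall", "phase1", "phase2", "phase3"]
        ].mean()
        dyads = sorted(per_dyad["dyad_id"].unique())

        def ip_vec(condition: str, col: str) -> np.ndarray:
            sub = per_dyad[per_dyad["condition"] == condition].set_index("dyad_id")[col]
            return sub.reindex(dyads).to_numpy()

        report["ip_overall_solo_vs_shared"] = _paired_contrast(
            "ip_overall_solo_vs_shared", ip_vec("shared", "overall"),
            ip_vec("solo", "overall"), alpha=alpha, d_convention=d_convention,
        )
        for k in (1, 2, 3):
            name = f"ip_phase{k}_solo_vs_shared"
            report[name] = _paired_contrast(
                name, ip_vec("shared", f"phase{k}"), ip_vec("solo", f"phase{k}"),
                alpha=alpha, d_convention=d_convention,
            )

        # condition x session two-way within design (needs >= 2 sessions)
        per_cell = ip.groupby(["dyad_id", "condition", "session"], as_index=False)[
            "overall"
        ].mean()
        sessions = sorted(per_cell["session"].unique())
        run_twoway = len(sessions) >= 2
        cube = np.full((len(dyads), 2, len(sessions)), np.nan)
        for i, d in enumerate(dyads):
            for j, c in enumerate(("solo", "shared")):
                for s, sess in enumerate(sessions):
                    cell = per_cell[
                        (per_cell["dyad_id"] == d)
                        & (per_cell["condition"] == c)
                        & (per_cell["session"] == sess)
                    ]["overall"]
                    if len(cell) == 1:
                        cube[i, j, s] = float(cell.iloc[0])
        if run_twoway:
            if np.any(~np.isfinite(cube)):
                raise IncompleteDesignError(
                    "missing condition x session cells in IP table"
                )
            cells = [cube[:, j, s] for j in range(2) for s in range(len(sessions))]
            normal, gates = _gate_normal(cells, alpha)
            if normal:
                effects = st.rm_anova_twoway(cube)
                branch = "parametric"
            else:
                effects = st.art_rm_anova(
                    cube, factor_names=("condition", "session", "condition:session")
                )
                effects = {
                    k: st.StatResult(r.test_name, r.statistic, r.df, r.p,
                                     r.effect_size, r.effect_size_type)
                    for k, r in effects.items()
                }
                branch = "rank"
            keymap = {"A": "condition", "B": "session", "A:B": "condition:session"}
            effects = {keymap.get(k, k): r for k, r in effects.items()}
            report["ip_condition_session_anova"] = BatteryEntry(
                "ip_condition_session_anova", branch, gates,
                effects["condition"], None,
                extra_results={"session": effects["session"],
                               "condition:session": effects["condition:session"]},
            )

    # --- embodiment ratings (participant level) -----------------------------
    if ratings is not None and len(ratings) > 0:
        wide_a = ratings.pivot(index="participant_id", columns="condition", values="agency")
        wide_o = ratings.pivot(index="participant_id", columns="condition", values="ownership")
        if {"solo", "shared"} - set(wide_a.columns):
            raise InvalidArgumentError("ratings must cover both conditions")
        a_solo = wide_a["solo"].to_numpy(dtype=float)
        a_shared = wide_a["shared"].to_numpy(dtype=float)
        o_solo = wide_o["solo"].to_numpy(dtype=float)
        o_shared = wide_o["shared"].to_numpy(dtype=float)

        report["agency_solo_vs_shared"] = _paired_contrast(
            "agency_solo_vs_shared", a_solo, a_shared, alpha=alpha, d_convention=d_convention
        )
        report["agency_solo_vs_100"] = _paired_contrast(
            "agency_solo_vs_100", a_solo, mu=100.0, alpha=alpha, d_convention=d_convention
        )
        report["agency_shared_vs_50"] = _paired_contrast(
            "agency_shared_vs_50", a_shared, mu=50.0, alpha=alpha, d_convention=d_convention
        )
        report["ownership_solo_vs_shared"] = _paired_contrast(
            "ownership_solo_vs_shared", o_solo, o_shared, alpha=alpha, d_convention=d_convention
        )

        # correlations with kinematics (participant level)
        part = aggregate_metrics(metrics, level="participant", actor="human")
        avatar = aggregate_metrics(metrics, level="dyad", actor="avatar")
        av_d = avatar[avatar["condition"] == "shared"].set_index("dyad_id")["D"]
        pj = part.pivot(index="participant_id", columns="condition", values="J")
        pd_dyad = part.drop_duplicates("participant_id").set_index("participant_id")["dyad_id"]
        idx = wide_o.index
        d_avatar = pd_dyad.reindex(idx).map(av_d).to_numpy(dtype=float)
        delta_j = (pj["shared"] - pj["solo"]).reindex(idx).to_numpy(dtype=float)
        delta_agency = a_shared - a_solo
        report["ownership_vs_avatar_deviation_corr"] = _correlation(
            "ownership_vs_avatar_deviation_corr", o_shared, d_avatar, alpha
        )
        report["agency_change_vs_jerk_change_corr"] = _correlation(
            "agency_change_vs_jerk_change_corr", delta_agency, delta_j, alpha
        )
    return report


def battery_frame(report: BatteryReport) -> pd.DataFrame:
    """Flatten a battery report into a tidy TSV-ready table."""
    rows = []
    for name, entry in report.items():
        results = {"": entry.result, **{f":{k}": r for k, r in entry.extra_results.items()}}
        for suffix, res in results.items():
            rows.append(
                {
                    "analysis": name + suffix,
                    "branch": entry.branch,
                    "test": res.test_name,
                    "statistic": res.statistic,
                    "df": "/".join(f"{d:g}" for d in res.df),
                    "p": res.p,
                    "effect_size": res.effect_size,
                    "effect_size_type": res.effect_size_type,
                    "adjustment": "",
                }
            )
        if entry.posthoc is not None:
            for c in entry.posthoc.contrasts:
                rows.append(
                    {
                        "analysis": f"{name}:{c.label}",
                        "branch": entry.branch,
                        "test": "posthoc_t",
                        "statistic": c.statistic,
                        "df": f"{c.df:g}",
                        "p": c.p_adjusted,
                        "effect_size": c.effect_size,
                        "effect_size_type": "standardized_diff",
                        "adjustment": entry.posthoc.adjustment_method,
                    }
                )
    return pd.DataFrame(rows)
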