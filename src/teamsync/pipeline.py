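"""End-to-end orchestration: simulate -> preprocess -> analyse -> compare.

The default study design mirrors a small pre-season block: three opposition
levels (first league, second league, amateur) with two matches each, ten
outfield players, one half per match. With opposition-dependent phase
coupling this yields the layouts the group comparisons expect: 45 dyads x 6
matches = 270 synchronization observations (ANOVA df 2, 267) and 10 players
x 6 matches = 60 time-motion observations (df 2, 57).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment, cluster_dyads
from .config import OPPOSITION_LEVELS, SimulationConfig
from .io import sync_records_frame
from .phase_sync import compute_dyad_sync
from .preprocess import preprocess_match
from .simulate import generate_field_vertices, generate_match
from .stats import AnovaResult, PairwiseEffect, lsd_pairwise, one_way_anova
from .time_motion import DEFAULT_SCHEME, summarize_time_motion

__all__ = ["StudyResults", "run_all", "run_match"]


@dataclass
class StudyResults:
    """All tables produced by one synthetic study."""

    metadata: pd.DataFrame          # match_id, opposition_level
    time_motion: pd.DataFrame       # per player x match distances
    sync: pd.DataFrame              # tidy dyad sync table (long format)
    clusters: dict                  # axis -> list[ClusterAssignment]
    anova: dict                     # outcome -> AnovaResult
    pairwise: dict                  # outcome -> list[PairwiseEffect]
    ground_truth: dict = field(default_factory=dict)  # match_id -> GroundTruth

    def anova_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"outcome": k, "F": a.F, "df_between": a.df_between,
             "df_within": a.df_within, "p": a.p,
             "partial_eta_sq": a.partial_eta_sq}
            for k, a in self.anova.items()
        ])

    def pairwise_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"outcome": k, "level_a": e.level_a, "level_b": e.level_b,
             "mean_diff": e.mean_diff, "lsd_p": e.lsd_p, "d": e.d,
             "d_ci_low": e.d_ci_low, "d_ci_high": e.d_ci_high}
            for k, effects in self.pairwise.items() for e in effects
        ])


def run_match(
    config: SimulationConfig,
    opposition_level: str,
    match_id: str,
    scheme=DEFAULT_SCHEME,
):
    """Simulate and fully analyse a single match half."""
    logs, truth = generate_match(config, opposition_level)
    vertices = generate_field_vertices(config)
    trajs, _geometry = preprocess_match(logs, vertices, rate=config.sample_rate)
    tm = [summarize_time_motion(tr, scheme, match_id=match_id)
          for tr in trajs.values()]
    sync = compute_dyad_sync(
        trajs, scheme, match_id=match_id, opposition_level=opposition_level
    )
    return trajs, tm, sync, truth


def run_all(
    base_config: SimulationConfig | None = None,
    seed: int = 0,
    matches_per_level: int = 2,
    levels: tuple = OPPOSITION_LEVELS,
    scheme=DEFAULT_SCHEME,
) -> StudyResults:
    """Run the full synthetic study and all group comparisons.

    Each match gets an independent child seed and its own field rotation,
    drawn once from the study seed, so the whole study is reproducible from
    a single integer.
    """
    if base_config is None:
        base_config = SimulationConfig()
    ss = np.random.SeedSequence(seed)
    match_seeds = ss.generate_state(len(levels) * matches_per_level * 2)

    meta_rows, tm_all, sync_all, truth_all = [], [], [], {}
    k = 0
    for level in levels:
        for _ in range(matches_per_level):
            match_id = f"M{k + 1:02d}"
            cfg = replace(
                base_config,
                seed=int(match_seeds[2 * k] % (2**31 - 1)),
                field_rotation_deg=float(match_seeds[2 * k + 1] % 180),
            )
            _trajs, tm, sync, truth = run_match(cfg, level, match_id, scheme)
            meta_rows.append({"match_id": match_id, "opposition_level": level})
            tm_all.extend(tm)
            sync_all.extend(sync)
            truth_all[match_id] = truth
            k += 1

    metadata = pd.DataFrame(meta_rows)
    tm_frame = pd.DataFrame([
        {"match_id": s.match_id, "player_id": s.player_id,
         "total_m": s.total_distance,
         **{f"{lab}_m": v for lab, v in s.distance_by_category.items()}}
        for s in tm_all
    ]).merge(metadata, on="match_id")
    sync_frame = sync_records_frame(sync_all)

    # dyad clustering feature: per-dyad mean overall sync % across matches
    clusters = {}
    overall = sync_frame[sync_frame["category"] == "overall"]
    for axis in ("x", "y"):
        sub = overall[overall["axis"] == axis]
        feat = (
            sub.groupby(["player_a", "player_b"])["pct_in_phase"]
            .mean()
            .to_dict()
        )
        clusters[axis] = cluster_dyads(feat, k=3, seed=seed, axis=axis)

    anova: dict[str, AnovaResult] = {}
    pairwise: dict[str, list[PairwiseEffect]] = {}

    def _compare(name, groups):
        a = one_way_anova(groups, outcome=name)
        anova[name] = a
        pairwise[name] = lsd_pairwise(groups, a)

    # time-motion outcomes: player x match observations per level
    for col, name in [("total_m", "total_distance")] + [
        (f"{lab}_m", f"distance_{lab}") for lab in scheme.labels
    ]:
        groups = {
            lvl: g[col].to_numpy()
            for lvl, g in tm_frame.groupby("opposition_level")
        }
        _compare(name, groups)

    # synchronization outcomes: dyad x match observations per level
    sync_meta = overall
    for axis in ("x", "y"):
        sub = sync_meta[sync_meta["axis"] == axis]
        groups = {
            lvl: g["pct_in_phase"].to_numpy()
            for lvl, g in sub.groupby("opposition_level")
        }
        _compare(f"sync_overall_{axis}", groups)
    for axis in ("x", "y"):
        for lab in scheme.labels:
            sub = sync_frame[
                (sync_frame["axis"] == axis) & (sync_frame["category"] == lab)
            ].dropna(subset=["pct_in_phase"])
            groups = {
                lvl: g["pct_in_phase"].to_numpy()
                for lvl, g in sub.groupby("opposition_level")
            }
            if all(len(v) >= 2 for v in groups.values()) and len(groups) >= 2:
                try:
                    _compare(f"sync_{lab}_{axis}", groups)
                except ValueError:
                    pass  # degenerate stratum (e.g. empty very-high bin)

    return StudyResults(
        metadata=metadata,
        time_motion=tm_frame,
        sync=sync_frame,
        clusters=clusters,
        anova=anova,
        pairwise=pairwise,
        ground_truth=truth_all,
    )
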