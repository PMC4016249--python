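"""Delimited-text readers and writers for every pipeline stage.

All tables are UTF-8 CSV with a header row. The position-log dialect is
match_id, player_id, unix_time_s, lat_deg, lon_deg; field vertices are four
lat_deg, lon_deg rows in perimeter order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment
from .phase_sync import DyadSyncRecord
from .preprocess import AlignedTrajectory
from .simulate import GroundTruth, RawPositionLog
from .time_motion import TimeMotionSummary

__all__ = [
    "write_positions", "read_positions",
    "write_field_vertices", "read_field_vertices",
    "write_trajectories", "read_trajectories",
    "write_time_motion", "write_sync_records", "sync_records_frame",
    "write_cluster_assignments", "write_ground_truth", "read_ground_truth",
]

POSITION_COLUMNS = ["match_id", "player_id", "unix_time_s", "lat_deg", "lon_deg"]


def write_positions(path, logs: list[RawPositionLog], match_id: str) -> None:
    frames = [
        pd.DataFrame({
            "match_id": match_id,
            "player_id": log.player_id,
            "unix_time_s": log.times,
            "lat_deg": log.lat,
            "lon_deg": log.lon,
        })
        for log in logs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_positions(path) -> dict[str, list[RawPositionLog]]:
    """Read a position-log table; returns {match_id: [RawPositionLog, ...]}."""
    df = pd.read_csv(path)
    missing = set(POSITION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"position file missing columns: {sorted(missing)}")
    out: dict[str, list[RawPositionLog]] = {}
    for (mid, pid), g in df.groupby(["match_id", "player_id"], sort=True):
        g = g.sort_values("unix_time_s")
        out.setdefault(str(mid), []).append(RawPositionLog(
            player_id=str(pid),
            times=g["unix_time_s"].to_numpy(dtype=float),
            lat=g["lat_deg"].to_numpy(dtype=float),
            lon=g["lon_deg"].to_numpy(dtype=float),
        ))
    return out


def write_field_vertices(path, vertices_latlon: np.ndarray) -> None:
    pd.DataFrame(vertices_latlon, columns=["lat_deg", "lon_deg"]).to_csv(
        path, index=False
    )


def read_field_vertices(path) -> np.ndarray:
    df = pd.read_csv(path)
    if list(df.columns) != ["lat_deg", "lon_deg"] or len(df) != 4:
        raise ValueError("field file must have 4 rows of lat_deg, lon_deg")
    return df.to_numpy(dtype=float)


def write_trajectories(path, trajs: dict[str, AlignedTrajectory], match_id: str) -> None:
    frames = [
        pd.DataFrame({
            "match_id": match_id,
            "player_id": tr.player_id,
            "t_s": tr.t,
            "x_m": tr.x,
            "y_m": tr.y,
            "interpolated_flag": (~tr.valid_mask).astype(int),
        })
        for tr in trajs.values()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path) -> dict[str, dict[str, AlignedTrajectory]]:
    df = pd.read_csv(path)
    out: dict[str, dict[str, AlignedTrajectory]] = {}
    for (mid, pid), g in df.groupby(["match_id", "player_id"], sort=True):
        g = g.sort_values("t_s")
        out.setdefault(str(mid), {})[str(pid)] = AlignedTrajectory(
            player_id=str(pid),
            t=g["t_s"].to_numpy(dtype=float),
            x=g["x_m"].to_numpy(dtype=float),
            y=g["y_m"].to_numpy(dtype=float),
            valid_mask=g["interpolated_flag"].to_numpy(dtype=int) == 0,
        )
    return out


def write_time_motion(path, summaries: list[TimeMotionSummary]) -> None:
    rows = []
    for s in summaries:
        row = {"match_id": s.match_id, "player_id": s.player_id,
               "total_m": s.total_distance}
        row.update({f"{lab}_m": v for lab, v in s.distance_by_category.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def sync_records_frame(records: list[DyadSyncRecord]) -> pd.DataFrame:
    """Tidy long-format frame: one row per dyad x axis x category
    (category 'overall' plus each speed category)."""
    rows = []
    for r in records:
        base = {
            "match_id": r.match_id, "player_a": r.dyad[0], "player_b": r.dyad[1],
            "axis": r.axis, "opposition_level": r.opposition_level,
        }
        rows.append({**base, "category": "overall",
                     "pct_in_phase": r.pct_in_phase_overall,
                     "n_samples": r.n_samples})
        for lab, pct in r.pct_in_phase_by_category.items():
            rows.append({**base, "category": lab, "pct_in_phase": pct,
                         "n_samples": r.n_samples_by_category[lab]})
    return pd.DataFrame(rows)


def write_sync_records(path, records: list[DyadSyncRecord]) -> None:
    sync_records_frame(records).to_csv(path, index=False)


def write_cluster_assignments(path, assignments: list[ClusterAssignment]) -> None:
    pd.DataFrame([
        {"axis": a.axis, "player_a": a.dyad[0], "player_b": a.dyad[1],
         "group": a.group, "centroid_pct": a.group_centroid,
         "group_sd_pct": a.group_sd}
        for a in assignments
    ]).to_csv(path, index=False)


def write_ground_truth(path, truth: GroundTruth) -> None:
    payload = {
        "player_offsets_deg": truth.player_offsets_deg,
        "dyad_offsets_deg": {
            ax: {f"{a}|{b}": v for (a, b), v in d.items()}
            for ax, d in truth.dyad_offsets_deg.items()
        },
        "kappa": truth.kappa,
        "field_rotation_deg": truth.field_rotation_deg,
        "opposition_level": truth.opposition_level,
        "anchors": truth.anchors,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        player_offsets_deg=payload["player_offsets_deg"],
        dyad_offsets_deg={
            ax: {tuple(k.split("|")): v for k, v in d.items()}
            for ax, d in payload["dyad_offsets_deg"].items()
        },
        kappa=payload["kappa"],
        field_rotation_deg=payload["field_rotation_deg"],
        opposition_level=payload["opposition_level"],
        anchors={k: tuple(v) for k, v in payload.get("anchors", {}).items()},
    )
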