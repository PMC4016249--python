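"""Speed, distance and intensity-category metrics per player.

Speeds are computed from consecutive pitch-plane displacements after
smoothing. Intensity categories follow the conventional GPS time-motion
bins: low < 3.6, moderate < 14.4, high < 19.8, very high >= 19.8 km/h,
implemented as contiguous half-open intervals so every finite speed maps to
exactly one category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import AlignedTrajectory

__all__ = [
    "SpeedCategoryScheme",
    "TimeMotionSummary",
    "compute_speed",
    "classify_speed",
    "summarize_time_motion",
]


@dataclass(frozen=True)
class SpeedCategoryScheme:
    """Ordered intensity bins over [0, inf), edges in km/h.

    Bin i covers [edge_{i-1}, edge_i) with edge_{-1}=0 and the last bin
    open-ended.
    """

    labels: tuple = ("low", "moderate", "high", "very_high")
    edges: tuple = (3.6, 14.4, 19.8)

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.labels) - 1:
            raise ValueError("need len(labels) - 1 edges")
        if list(self.edges) != sorted(self.edges) or self.edges[0] <= 0:
            raise ValueError("edges must be positive and increasing")


DEFAULT_SCHEME = SpeedCategoryScheme()


@dataclass
class TimeMotionSummary:
    """Per-player distance and time totals, overall and per category."""

    player_id: str
    match_id: str
    total_distance: float                 # m
    distance_by_category: dict            # label -> m
    time_by_category: dict                # label -> s

    def __post_init__(self) -> None:
        s = sum(self.distance_by_category.values())
        if abs(s - self.total_distance) > 1e-6:
            raise ValueError("category distances do not sum to total")
        if any(v < -1e-12 for v in self.distance_by_category.values()):
            raise ValueError("negative distance")


def compute_speed(traj: AlignedTrajectory) -> np.ndarray:
    """Instantaneous speed per sample in km/h.

    speed_i is the planar displacement from sample i-1 to i times the
    sampling rate; the first sample replicates the second's speed so the
    series matches the trajectory length.
    """
    if len(traj.t) < 2:
        raise ValueError("need at least 2 samples to compute speed")
    rate = traj.rate
    disp = np.hypot(np.diff(traj.x), np.diff(traj.y))
    speed = np.empty(len(traj.t))
    speed[1:] = disp * rate * 3.6
    speed[0] = speed[1]
    return speed


def classify_speed(
    speed, scheme: SpeedCategoryScheme = DEFAULT_SCHEME
) -> np.ndarray:
    """Map speeds (km/h) to category labels by left-closed binning."""
    s = np.asarray(speed, dtype=float)
    if np.any(~np.isfinite(s)) or np.any(s < 0):
        raise ValueError("speeds must be finite and non-negative")
    idx = np.searchsorted(np.asarray(scheme.edges), s, side="right")
    labels = np.asarray(scheme.labels, dtype=object)
    if np.ndim(speed) == 0:
        return str(labels[int(idx)])
    return labels[idx]


def summarize_time_motion(
    traj: AlignedTrajectory,
    scheme: SpeedCategoryScheme = DEFAULT_SCHEME,
    match_id: str = "",
) -> TimeMotionSummary:
    """Accumulate displacement and dwell time into intensity categories.

    Each inter-sample displacement is credited to the category of the
    arriving sample's speed, so category distances partition the total
    exactly. Dwell time counts every sample at the sampling period.
    """
    speed = compute_speed(traj)
    cats = classify_speed(speed, scheme)
    disp = np.hypot(np.diff(traj.x), np.diff(traj.y))
    dt = 1.0 / traj.rate

    dist = {lab: 0.0 for lab in scheme.labels}
    time = {lab: 0.0 for lab in scheme.labels}
    for lab in scheme.labels:
        sel = cats == lab
        dist[lab] = float(disp[sel[1:]].sum())
        time[lab] = float(sel.sum() * dt)
    return TimeMotionSummary(
        player_id=traj.player_id,
        match_id=match_id,
        total_distance=float(sum(dist.values())),
        distance_by_category=dist,
        time_by_category=time,
    )
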