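"""Raw GPS logs -> synchronized, smoothed, pitch-aligned metric trajectories.

The chain is: resample every player onto one shared 5 Hz time base (linear
interpolation over dropouts, intersection of coverage across players),
project lat/lon to UTM metres, estimate the pitch orientation from the four
field vertices, rotate all positions so the field length lies along x and
the width along y, and low-pass the result with a zero-phase Butterworth
filter. Interpolated samples are flagged so downstream sensitivity to gap
filling stays auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .geo import latlon_to_utm
from .simulate import RawPositionLog

__all__ = [
    "FieldGeometry",
    "AlignedTrajectory",
    "synchronize_and_interpolate",
    "fit_rotation",
    "apply_rotation",
    "lowpass_smooth",
    "preprocess_match",
]

DEFAULT_CUTOFF_HZ = 3.0  # nominal smoothing cutoff; clamped below Nyquist


@dataclass
class FieldGeometry:
    """Projected field vertices (m, perimeter order) and pitch angle.

    ``theta`` is the direction of the field's long side from the x-axis,
    degrees in [0, 180).
    """

    vertices: np.ndarray  # (4, 2) metric
    theta: float

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)


@dataclass
class AlignedTrajectory:
    """One player's gap-free pitch-aligned trajectory on a uniform grid.

    x is the longitudinal coordinate (m, along the field length), y the
    lateral one. ``valid_mask`` is False where the sample was interpolated.
    """

    player_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid_mask) == n):
            raise ValueError("t/x/y/valid_mask length mismatch")
        if np.any(~np.isfinite(self.x)) or np.any(~np.isfinite(self.y)):
            raise ValueError("trajectory contains non-finite values")

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))


def synchronize_and_interpolate(
    logs: list[RawPositionLog], rate: float = 5.0
) -> dict[str, dict]:
    """Resample all players onto one uniform time base.

    The base is the intersection of the players' coverage (no
    extrapolation); interior gaps are filled by linear interpolation of
    each coordinate. Returns ``{player_id: {t, lat, lon, valid_mask}}``.
    """
    if not logs:
        raise ValueError("no position logs given")
    for log in logs:
        if len(log.times) < 2:
            raise ValueError(f"player {log.player_id}: fewer than 2 samples")
    start = max(float(log.times[0]) for log in logs)
    end = min(float(log.times[-1]) for log in logs)
    if end <= start:
        raise ValueError("players have no common time coverage")
    dt = 1.0 / rate
    n = int(np.floor((end - start) / dt + 1e-9)) + 1
    t = start + np.arange(n) * dt

    out: dict[str, dict] = {}
    tol = 0.25 * dt
    for log in logs:
        lat = np.interp(t, log.times, log.lat)
        lon = np.interp(t, log.times, log.lon)
        # a grid sample is "observed" if a raw sample sits within a quarter
        # period of it; otherwise it was reconstructed
        idx = np.searchsorted(log.times, t)
        idx_lo = np.clip(idx - 1, 0, len(log.times) - 1)
        idx_hi = np.clip(idx, 0, len(log.times) - 1)
        nearest = np.minimum(
            np.abs(log.times[idx_lo] - t), np.abs(log.times[idx_hi] - t)
        )
        out[log.player_id] = {
            "t": t,
            "lat": lat,
            "lon": lon,
            "valid_mask": nearest <= tol,
        }
    return out


def fit_rotation(field: FieldGeometry | np.ndarray) -> float:
    """Pitch angle theta (deg, [0, 180)) from four projected vertices.

    Vertices are taken in perimeter order; the two opposite sides of the
    longer pair define the long axis, and their directions are averaged on
    the half-circle (period 180 deg).
    """
    v = field.vertices if isinstance(field, FieldGeometry) else np.asarray(field, float)
    if v.shape != (4, 2):
        raise ValueError("expected four planar vertices")
    sides = np.roll(v, -1, axis=0) - v  # s0..s3 in perimeter order
    lengths = np.hypot(sides[:, 0], sides[:, 1])
    if np.any(lengths < 1e-9):
        raise ValueError("degenerate field vertices (coincident points)")
    cross = abs(sides[0][0] * sides[1][1] - sides[0][1] * sides[1][0])
    if cross < 1e-6 * lengths[0] * lengths[1]:
        raise ValueError("degenerate field vertices (collinear)")
    for pair in ((0, 2), (1, 3)):
        la, lb = lengths[pair[0]], lengths[pair[1]]
        if abs(la - lb) > 0.05 * max(la, lb):
            warnings.warn(
                "opposite field sides differ by more than 5%; "
                "vertices may not form a rectangle",
                stacklevel=2,
            )
    long_pair = (0, 2) if lengths[[0, 2]].mean() >= lengths[[1, 3]].mean() else (1, 3)
    # average directions on the half-circle by doubling the angles
    angles = np.array([
        np.arctan2(sides[i][1], sides[i][0]) for i in long_pair
    ])
    mean2 = np.arctan2(np.sin(2 * angles).sum(), np.cos(2 * angles).sum())
    theta = np.degrees(mean2 / 2.0) % 180.0
    if theta >= 180.0 - 1e-9:  # numerical wrap at the half-circle seam
        theta = 0.0
    return float(theta)


def apply_rotation(
    points: np.ndarray, theta: float, center: np.ndarray | None = None
) -> np.ndarray:
    """Rotate points by -theta (deg) about ``center`` (default: centroid).

    Aligns the field's long axis with x; an isometry, so all pairwise
    distances are preserved.
    """
    pts = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite points")
    c = pts.mean(axis=0) if center is None else np.asarray(center, dtype=float)
    th = np.radians(-theta)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return (pts - c) @ rot.T + c


def lowpass_smooth(series: np.ndarray, cutoff: float, rate: float) -> np.ndarray:
    """Zero-phase (forward-backward) 2nd-order Butterworth low-pass.

    A cutoff at or above the Nyquist frequency is clamped to 0.99 x Nyquist
    with a warning; the dual pass doubles the effective order and cancels
    phase delay.
    """
    series = np.asarray(series, dtype=float)
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    nyq = rate / 2.0
    if cutoff >= nyq:
        warnings.warn(
            f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz; clamping to {0.99 * nyq} Hz",
            stacklevel=2,
        )
        cutoff = 0.99 * nyq
    b, a = signal.butter(2, cutoff / nyq)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if len(series) <= padlen:
        raise ValueError(
            f"series of length {len(series)} shorter than filter warm-up {padlen}"
        )
    return signal.filtfilt(b, a, series)


def preprocess_match(
    logs: list[RawPositionLog],
    field_vertices_latlon: np.ndarray,
    rate: float = 5.0,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    smooth: bool = True,
) -> tuple[dict[str, AlignedTrajectory], FieldGeometry]:
    """Full preprocessing chain for one match.

    Returns pitch-aligned trajectories (origin at the field centre) and the
    fitted field geometry. Deterministic: same input, same output.
    """
    synced = synchronize_and_interpolate(logs, rate=rate)

    all_lon = np.concatenate(
        [np.asarray(field_vertices_latlon)[:, 1]]
        + [s["lon"] for s in synced.values()]
    )
    all_lat = np.concatenate(
        [np.asarray(field_vertices_latlon)[:, 0]]
        + [s["lat"] for s in synced.values()]
    )
    e, n, zone = latlon_to_utm(all_lat, all_lon)
    fv = np.column_stack([e[:4], n[:4]])
    theta = fit_rotation(fv)
    geometry = FieldGeometry(vertices=fv, theta=theta)
    center = geometry.centroid
    aligned_vertices = apply_rotation(fv, theta, center=center) - center

    trajs: dict[str, AlignedTrajectory] = {}
    offset = 4
    for pid, s in synced.items():
        m = len(s["t"])
        pts = np.column_stack([e[offset:offset + m], n[offset:offset + m]])
        offset += m
        xy = apply_rotation(pts, theta, center=center) - center
        x, y = xy[:, 0], xy[:, 1]
        if smooth:
            x = lowpass_smooth(x, cutoff_hz, rate)
            y = lowpass_smooth(y, cutoff_hz, rate)
        half_len = 0.5 * np.ptp(aligned_vertices[:, 0])
        half_wid = 0.5 * np.ptp(aligned_vertices[:, 1])
        if np.max(np.abs(x)) > 1.5 * half_len or np.max(np.abs(y)) > 1.5 * half_wid:
            warnings.warn(
                f"player {pid} strays far outside the field footprint",
                stacklevel=2,
            )
        trajs[pid] = AlignedTrajectory(
            player_id=pid, t=s["t"], x=x, y=y, valid_mask=s["valid_mask"]
        )
    return trajs, geometry
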