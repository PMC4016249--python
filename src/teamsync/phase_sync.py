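"""Dyadic movement synchronization via Hilbert-transform relative phase.

Each player's pitch-aligned coordinate series (per axis) is centred and
passed through the analytic-signal transform; the angle of the analytic
signal is the instantaneous phase. For every unordered pair of players (a
dyad — 45 pairs for 10 outfield players) the wrapped phase difference is
computed per sample, and synchronization is summarized as the percentage of
samples whose relative phase falls in the near-in-phase band [-30, 30]
degrees, overall and stratified by the dyad's average movement speed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.signal import hilbert

from .preprocess import AlignedTrajectory
from .simulate import wrap_degrees
from .time_motion import DEFAULT_SCHEME, SpeedCategoryScheme, classify_speed, compute_speed

__all__ = [
    "PhaseSeries",
    "RelativePhaseSeries",
    "DyadSyncRecord",
    "IN_PHASE_BAND",
    "instantaneous_phase",
    "relative_phase",
    "percent_in_band",
    "dyad_speed_category",
    "compute_dyad_sync",
]

IN_PHASE_BAND = (-30.0, 30.0)


@dataclass
class PhaseSeries:
    """Instantaneous phase of one player's movement along one axis,
    degrees wrapped to (-180, 180]."""

    player_id: str
    axis: str
    phi: np.ndarray


@dataclass
class RelativePhaseSeries:
    """Wrapped phase difference phi_a - phi_b for a canonical dyad
    (lexicographic player order fixes the sign)."""

    dyad: tuple
    axis: str
    rel_phi: np.ndarray


@dataclass
class DyadSyncRecord:
    """Near-in-phase synchronization of one dyad on one axis.

    Percentages are of samples in the closed band; per-category values are
    relative to the samples belonging to that dyad-average-speed category
    (NaN where a category has no samples).
    """

    match_id: str
    dyad: tuple
    axis: str
    pct_in_phase_overall: float
    pct_in_phase_by_category: dict
    n_samples_by_category: dict
    n_samples: int
    opposition_level: str = ""


def instantaneous_phase(
    series: np.ndarray, player_id: str = "", axis: str = "x",
    detrend_window_s: float | None = None, rate: float = 5.0,
) -> PhaseSeries:
    """Phase (deg) of the analytic signal of a centred coordinate series.

    The series mean is removed before the transform; optionally a moving-
    average trend over ``detrend_window_s`` seconds is subtracted instead,
    which guards against slow team drift biasing the analytic signal's
    centre.
    """
    s = np.asarray(series, dtype=float)
    if len(s) < 64:
        raise ValueError("need at least 64 samples for a stable phase estimate")
    if np.ptp(s) < 1e-12:
        raise ValueError("constant series has no defined phase")
    if detrend_window_s:
        w = max(3, int(round(detrend_window_s * rate)) | 1)
        kernel = np.ones(w) / w
        pad = np.pad(s, w // 2, mode="edge")
        trend = np.convolve(pad, kernel, mode="valid")
        centred = s - trend
    else:
        centred = s - s.mean()
    phi = np.degrees(np.angle(hilbert(centred)))
    return PhaseSeries(player_id=player_id, axis=axis, phi=wrap_degrees(phi))


def relative_phase(a: PhaseSeries, b: PhaseSeries) -> RelativePhaseSeries:
    """Per-sample wrapped phase difference of a dyad.

    Players are put in lexicographic order, so swapping the arguments
    returns the pointwise negation (up to the 180 == -180 identification).
    """
    if a.axis != b.axis:
        raise ValueError(f"axis mismatch: {a.axis} vs {b.axis}")
    if len(a.phi) != len(b.phi):
        raise ValueError("phase series length mismatch")
    first, second = (a, b) if a.player_id <= b.player_id else (b, a)
    rel = wrap_degrees(first.phi - second.phi)
    return RelativePhaseSeries(
        dyad=(first.player_id, second.player_id), axis=a.axis, rel_phi=rel
    )


def percent_in_band(
    rel: RelativePhaseSeries | np.ndarray,
    lo: float = IN_PHASE_BAND[0],
    hi: float = IN_PHASE_BAND[1],
    mask: np.ndarray | None = None,
) -> tuple[float, int]:
    """Percentage of samples with relative phase in the closed band [lo, hi].

    Returns ``(pct, n)`` where n is the number of samples considered; an
    empty mask yields ``(nan, 0)``.
    """
    if lo >= hi:
        raise ValueError("need lo < hi")
    phi = rel.rel_phi if isinstance(rel, RelativePhaseSeries) else np.asarray(rel)
    if mask is not None:
        phi = phi[np.asarray(mask, dtype=bool)]
    n = len(phi)
    if n == 0:
        return float("nan"), 0
    inside = np.count_nonzero((phi >= lo) & (phi <= hi))
    return 100.0 * inside / n, n


def dyad_speed_category(
    speed_a: np.ndarray,
    speed_b: np.ndarray,
    scheme: SpeedCategoryScheme = DEFAULT_SCHEME,
) -> np.ndarray:
    """Per-sample intensity category of the dyad's mean speed (km/h)."""
    sa, sb = np.asarray(speed_a, float), np.asarray(speed_b, float)
    if sa.shape != sb.shape:
        raise ValueError("speed series length mismatch")
    return classify_speed((sa + sb) / 2.0, scheme)


def compute_dyad_sync(
    trajectories: dict[str, AlignedTrajectory],
    scheme: SpeedCategoryScheme = DEFAULT_SCHEME,
    band: tuple[float, float] = IN_PHASE_BAND,
    match_id: str = "",
    opposition_level: str = "",
    detrend_window_s: float | None = None,
) -> list[DyadSyncRecord]:
    """Near-in-phase percentages for every dyad on both pitch axes.

    For n players this yields n(n-1)/2 records per axis (45 for 10). The
    per-category stratification uses the dyad's per-sample mean speed.
    """
    ids = sorted(trajectories)
    if len(ids) < 2:
        raise ValueError("need at least 2 players")
    lengths = {len(trajectories[i].t) for i in ids}
    if len(lengths) != 1:
        raise ValueError("trajectories are not on a common time base")

    phases = {}
    speeds = {}
    for pid in ids:
        tr = trajectories[pid]
        rate = tr.rate
        for axis, series in (("x", tr.x), ("y", tr.y)):
            phases[pid, axis] = instantaneous_phase(
                series, pid, axis, detrend_window_s=detrend_window_s, rate=rate
            )
        speeds[pid] = compute_speed(tr)

    records: list[DyadSyncRecord] = []
    for a, b in combinations(ids, 2):
        cats = dyad_speed_category(speeds[a], speeds[b], scheme)
        for axis in ("x", "y"):
            rel = relative_phase(phases[a, axis], phases[b, axis])
            pct_all, n_all = percent_in_band(rel, *band)
            pct_by, n_by = {}, {}
            for lab in scheme.labels:
                pct_c, n_c = percent_in_band(rel, *band, mask=cats == lab)
                pct_by[lab] = pct_c
                n_by[lab] = n_c
            records.append(DyadSyncRecord(
                match_id=match_id,
                dyad=(a, b),
                axis=axis,
                pct_in_phase_overall=pct_all,
                pct_in_phase_by_category=pct_by,
                n_samples_by_category=n_by,
                n_samples=n_all,
                opposition_level=opposition_level,
            ))
    return records
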