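"""Synthetic match generator with known ground truth.

Players are modelled as phase-coupled oscillators: each player moves around
a role anchor (a nominal 4-4-2 formation) following a shared sinusoidal
oscillation per pitch axis, with an individual phase offset drawn from a
von Mises distribution centred on zero. The concentration kappa is the
coupling knob: kappa -> infinity collapses all offsets to zero (perfect
in-phase movement), kappa = 0 scatters them uniformly on the circle. A slow
constant-speed circular drift of the whole team and Gaussian positional
jitter complete the kinematics. Positions are laid out on a rotated pitch,
georeferenced through the inverse UTM projection, and optionally punctured
with sampling gaps, so the raw output looks like real 5 Hz GPS logs while
every imposed phase relation is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig, OPPOSITION_LEVELS
from .geo import latlon_to_utm, utm_to_latlon

__all__ = [
    "RawPositionLog",
    "GroundTruth",
    "generate_match",
    "generate_field_vertices",
    "role_anchors",
    "wrap_degrees",
]


@dataclass
class RawPositionLog:
    """Per-player timestamped lat/lon samples, possibly with gaps."""

    player_id: str
    times: np.ndarray      # seconds (unix-like offset), strictly increasing
    lat: np.ndarray        # decimal degrees
    lon: np.ndarray        # decimal degrees
    nominal_rate: float = 5.0

    def __post_init__(self) -> None:
        if len(self.times) != len(self.lat) or len(self.times) != len(self.lon):
            raise ValueError("times/lat/lon length mismatch")
        if len(self.times) >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.abs(self.lat) > 90) or np.any(np.abs(self.lon) > 180):
            raise ValueError("lat/lon out of range")


@dataclass
class GroundTruth:
    """Imposed parameters recorded for downstream recovery checks.

    Phase offsets are in degrees wrapped to (-180, 180]; dyad offsets are
    the wrapped differences of the two players' offsets, keyed by
    lexicographically ordered player-id pairs.
    """

    player_offsets_deg: dict  # axis -> {player_id: offset}
    dyad_offsets_deg: dict    # axis -> {(id_a, id_b): wrapped difference}
    kappa: dict               # axis -> concentration used
    field_rotation_deg: float
    opposition_level: str
    anchors: dict = field(default_factory=dict)  # player_id -> (x, y) m


def wrap_degrees(deg):
    """Wrap angles in degrees to (-180, 180]."""
    wrapped = -((-np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0)
    return wrapped


def role_anchors(n_players: int, field_length: float, field_width: float):
    """Nominal anchor positions (m, pitch frame centred on the field centre).

    For 10 players: 4 defenders, 4 midfielders, 2 forwards. Other counts
    fill the same three lines in proportion.
    """
    if n_players == 10:
        lines = [(-0.28 * field_length, 4), (0.0, 4), (0.24 * field_length, 2)]
    else:
        nd = max(1, round(0.4 * n_players))
        nf = max(1, round(0.2 * n_players))
        nm = max(1, n_players - nd - nf)
        lines = [(-0.28 * field_length, nd), (0.0, nm), (0.24 * field_length, nf)]
    anchors = []
    for x_line, count in lines:
        ys = np.linspace(-0.35 * field_width, 0.35 * field_width, count)
        anchors.extend((x_line, y) for y in ys)
    return np.array(anchors[:n_players])


def _field_frame_to_latlon(xy: np.ndarray, config: SimulationConfig):
    """Rotate pitch-frame coords by the field angle, translate to the pitch
    centre's UTM position, and invert the projection to lat/lon."""
    th = np.radians(config.field_rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    enu = xy @ rot.T
    e0, n0, zone = latlon_to_utm(config.field_origin_lat, config.field_origin_lon)
    lat, lon = utm_to_latlon(enu[..., 0] + e0, enu[..., 1] + n0, zone)
    return lat, lon


def generate_field_vertices(config: SimulationConfig) -> np.ndarray:
    """Four pitch corner vertices in perimeter order as (lat, lon) rows.

    The rectangle is field_length x field_width, rotated by
    ``field_rotation_deg`` about its centre.
    """
    hl, hw = config.field_length / 2.0, config.field_width / 2.0
    corners = np.array([[-hl, -hw], [hl, -hw], [hl, hw], [-hl, hw]])
    lat, lon = _field_frame_to_latlon(corners, config)
    return np.column_stack([lat, lon])


def generate_match(
    config: SimulationConfig,
    opposition_level: str = "second_league",
) -> tuple[list[RawPositionLog], GroundTruth]:
    """Simulate one match half and return raw GPS logs plus ground truth.

    Identical config (including seed) gives byte-identical output.
    """
    if opposition_level not in OPPOSITION_LEVELS:
        raise ValueError(
            f"unknown opposition level {opposition_level!r}; "
            f"expected one of {OPPOSITION_LEVELS}"
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    t = np.arange(n) / config.sample_rate
    ids = [f"P{i + 1:02d}" for i in range(config.n_players)]
    anchors = role_anchors(config.n_players, config.field_length, config.field_width)

    kappa = {ax: config.kappa_for(opposition_level, ax) for ax in ("x", "y")}
    offsets = {}
    for ax in ("x", "y"):
        if kappa[ax] >= 1e6:  # degenerate concentration: exact in-phase
            off = np.zeros(config.n_players)
        else:
            off = rng.vonmises(0.0, kappa[ax], size=config.n_players)
        offsets[ax] = off  # radians for now

    # shared slow drift: uniform circular motion at exactly drift_speed
    if config.drift_speed > 0:
        om_d = 2.0 * np.pi / config.drift_period
        r_d = config.drift_speed / om_d
        psi = rng.uniform(0, 2 * np.pi)
        drift_x = r_d * (np.cos(om_d * t + psi) - np.cos(psi))
        drift_y = r_d * (np.sin(om_d * t + psi) - np.sin(psi))
    else:
        drift_x = np.zeros(n)
        drift_y = np.zeros(n)

    om_x = 2.0 * np.pi / config.base_period_x
    om_y = 2.0 * np.pi / config.base_period_y

    logs: list[RawPositionLog] = []
    for i, pid in enumerate(ids):
        x = (anchors[i, 0] + drift_x
             + config.osc_amp_x * np.sin(om_x * t + offsets["x"][i]))
        y = (anchors[i, 1] + drift_y
             + config.osc_amp_y * np.sin(om_y * t + offsets["y"][i]))
        if config.noise_sd > 0:
            x = x + rng.normal(0.0, config.noise_sd, n)
            y = y + rng.normal(0.0, config.noise_sd, n)
        lat, lon = _field_frame_to_latlon(np.column_stack([x, y]), config)

        keep = np.ones(n, dtype=bool)
        if config.gap_fraction > 0:
            n_del = int(round(config.gap_fraction * n))
            interior = np.arange(1, n - 1)
            drop = rng.choice(interior, size=min(n_del, len(interior)),
                              replace=False)
            keep[drop] = False
        logs.append(RawPositionLog(
            player_id=pid,
            times=t[keep],
            lat=np.asarray(lat)[keep],
            lon=np.asarray(lon)[keep],
            nominal_rate=config.sample_rate,
        ))

    player_off_deg = {
        ax: {pid: float(wrap_degrees(np.degrees(offsets[ax][i])))
             for i, pid in enumerate(ids)}
        for ax in ("x", "y")
    }
    dyad_off_deg = {
        ax: {
            (a, b): float(wrap_degrees(player_off_deg[ax][a] - player_off_deg[ax][b]))
            for ia, a in enumerate(ids) for b in ids[ia + 1:]
        }
        for ax in ("x", "y")
    }
    truth = GroundTruth(
        player_offsets_deg=player_off_deg,
        dyad_offsets_deg=dyad_off_deg,
        kappa=kappa,
        field_rotation_deg=config.field_rotation_deg,
        opposition_level=opposition_level,
        anchors={pid: (float(anchors[i, 0]), float(anchors[i, 1]))
                 for i, pid in enumerate(ids)},
    )
    return logs, truth
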