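"""Simulation configuration for synthetic matches.

The generator drives every downstream stage with known ground truth, so its
defaults define the study conditions: ten outfield players tracked at 5 Hz
for one 45-minute half on a 105 x 68 m pitch, with per-axis phase coupling
controlled by a von Mises concentration kappa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

__all__ = ["SimulationConfig", "OPPOSITION_LEVELS", "KAPPA_PRESETS"]

OPPOSITION_LEVELS = ("first_league", "second_league", "amateur")

# Coupling presets per opposition level (both axes). Stronger opponents
# induce tighter in-phase coupling, which is the qualitative effect the
# downstream statistics are designed to detect. Override by setting
# kappa_x / kappa_y explicitly on the config.
KAPPA_PRESETS: dict[str, float] = {
    "first_league": 32.0,
    "second_league": 8.0,
    "amateur": 2.0,
}


@dataclass
class SimulationConfig:
    """Parameters of one simulated match half.

    Attributes
    ----------
    n_players:
        Outfield players per team (10 in a standard 11-a-side line-up).
    duration:
        Simulated time in seconds; 2700 s is one half.
    sample_rate:
        GPS sampling rate in Hz.
    field_length, field_width:
        Pitch dimensions in metres.
    field_rotation_deg:
        Orientation of the pitch long axis relative to grid east, degrees.
    field_origin_lat, field_origin_lon:
        Geographic position of the pitch centre, decimal degrees.
    kappa_x, kappa_y:
        von Mises concentration of player phase offsets per axis; 0 means
        uncoupled (uniform offsets), large values mean near-perfect
        in-phase coupling. ``None`` defers to the opposition-level preset.
    base_period_x, base_period_y:
        Period (s) of the team's shared positional oscillation per axis.
    osc_amp_x, osc_amp_y:
        Oscillation amplitudes in metres; the defaults make instantaneous
        speeds span all four intensity categories.
    drift_speed:
        Speed (m/s) of a slow shared drift of the whole team, modelled as
        uniform circular motion so the speed is constant and the team stays
        on the pitch.
    drift_period:
        Period (s) of the drift loop.
    noise_sd:
        Positional jitter standard deviation per axis, metres.
    gap_fraction:
        Fraction of interior samples deleted per player to emulate GPS
        dropouts; must be < 0.5.
    seed:
        Seed for all randomness; identical seeds give identical matches.
    """

    n_players: int = 10
    duration: float = 2700.0
    sample_rate: float = 5.0
    field_length: float = 105.0
    field_width: float = 68.0
    field_rotation_deg: float = 17.0
    field_origin_lat: float = 41.55
    field_origin_lon: float = -8.42
    kappa_x: float | None = None
    kappa_y: float | None = None
    base_period_x: float = 20.0
    base_period_y: float = 15.0
    osc_amp_x: float = 15.0
    osc_amp_y: float = 8.0
    drift_speed: float = 0.3
    drift_period: float = 120.0
    noise_sd: float = 0.3
    gap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        numeric = {
            k: v for k, v in asdict(self).items()
            if isinstance(v, (int, float)) and v is not None
        }
        for k, v in numeric.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite config value: {k}={v}")
        if self.n_players < 2:
            raise ValueError("n_players must be >= 2")
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be positive")
        n = self.duration * self.sample_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"duration*sample_rate must be an integer sample count, got {n}"
            )
        for name in ("kappa_x", "kappa_y"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.gap_fraction < 0.5:
            raise ValueError("gap_fraction must be in [0, 0.5)")
        if self.noise_sd < 0 or self.drift_speed < 0:
            raise ValueError("noise_sd and drift_speed must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate)) + 1

    def kappa_for(self, opposition_level: str, axis: str) -> float:
        """Coupling for one axis: explicit config value, else level preset."""
        explicit = self.kappa_x if axis == "x" else self.kappa_y
        if explicit is not None:
            return float(explicit)
        if opposition_level not in KAPPA_PRESETS:
            raise ValueError(
                f"unknown opposition level {opposition_level!r}; "
                f"expected one of {OPPOSITION_LEVELS}"
            )
        return KAPPA_PRESETS[opposition_level]
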