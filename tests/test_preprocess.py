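"""Preprocessing: interpolation, rotation recovery, filtering, round trips."""

import warnings
from dataclasses import replace

import numpy as np
import pytest
from scipy import signal

from teamsync import (
    RawPositionLog,
    SimulationConfig,
    apply_rotation,
    fit_rotation,
    generate_field_vertices,
    generate_match,
    lowpass_smooth,
    preprocess_match,
    synchronize_and_interpolate,
)
from teamsync.geo import latlon_to_utm, utm_to_latlon
from teamsync.preprocess import FieldGeometry


def _log_from_metric(player_id, t, x, y, lat0=41.55, lon0=-8.42):
    """Build a lat/lon log whose projected coordinates are (x, y) metres
    offset from a reference point."""
    e0, n0, zone = latlon_to_utm(lat0, lon0)
    lat, lon = utm_to_latlon(e0 + np.asarray(x, float),
                             n0 + np.asarray(y, float), zone)
    return RawPositionLog(player_id=player_id, times=np.asarray(t, float),
                          lat=np.atleast_1d(lat), lon=np.atleast_1d(lon))


class TestSynchronizeInterpolate:
    def test_uniform_gapless_input_is_identity(self):
        t = np.arange(50) / 5.0
        log = _log_from_metric("A", t, t * 1.5, np.zeros_like(t))
        out = synchronize_and_interpolate([log], rate=5.0)["A"]
        assert np.allclose(out["t"], t)
        assert np.allclose(out["lat"], log.lat)
        assert out["valid_mask"].all()

    def test_single_missing_sample_fills_linear_midpoint(self):
        t_full = np.arange(30) / 5.0
        x = np.linspace(0.0, 29.0, 30)  # 10 m at i=10, 12 m at i=12
        keep = np.ones(30, bool)
        keep[11] = False
        log = _log_from_metric("A", t_full[keep], x[keep], np.zeros(keep.sum()))
        out = synchronize_and_interpolate([log], rate=5.0)["A"]
        e, n, z = latlon_to_utm(out["lat"], out["lon"])
        e0, n0, _ = latlon_to_utm(41.55, -8.42)
        filled = (e - e0)[11]
        assert filled == pytest.approx((x[10] + x[12]) / 2.0, abs=1e-6)
        assert not out["valid_mask"][11]
        assert out["valid_mask"].sum() == 29

    def test_common_base_is_intersection_of_coverage(self):
        t = np.arange(100) / 5.0
        a = _log_from_metric("A", t, t, np.zeros_like(t))
        b = _log_from_metric("B", t[10:80], t[10:80], np.zeros(70))
        out = synchronize_and_interpolate([a, b], rate=5.0)
        assert out["A"]["t"][0] == pytest.approx(2.0)
        assert out["A"]["t"][-1] == pytest.approx(t[79])
        assert len(out["A"]["t"]) == len(out["B"]["t"]) == 70

    def test_errors_on_too_few_samples_and_disjoint_coverage(self):
        t = np.arange(20) / 5.0
        good = _log_from_metric("A", t, t, np.zeros_like(t))
        with pytest.raises(ValueError, match="fewer than 2"):
            synchronize_and_interpolate(
                [good, _log_from_metric("B", [0.0], [0.0], [0.0])]
            )
        late = _log_from_metric("C", t + 100.0, t, np.zeros_like(t))
        with pytest.raises(ValueError, match="common time coverage"):
            synchronize_and_interpolate([good, late])

    def test_interpolated_gap_error_bounded_by_curvature(self):
        # Oracle re-simulation: the same seed without gaps provides the
        # noise-free truth; linear interpolation error over a gap of g
        # samples is bounded by |a|max (g dt)^2 / 8 for a smooth path.
        cfg = SimulationConfig(duration=300.0, noise_sd=0.0, drift_speed=0.0,
                               gap_fraction=0.1, seed=21)
        cfg_full = replace(cfg, gap_fraction=0.0)
        gapped, _ = generate_match(cfg, "amateur")
        full, _ = generate_match(cfg_full, "amateur")
        out_g = synchronize_and_interpolate(gapped, rate=5.0)
        out_f = synchronize_and_interpolate(full, rate=5.0)
        dt = 0.2
        om = 2 * np.pi / cfg.base_period_x
        a_max = cfg.osc_amp_x * om**2 + cfg.osc_amp_y * (2 * np.pi / cfg.base_period_y) ** 2
        for log in gapped:
            gaps = np.diff(log.times)
            g_max = round(float(gaps.max()) / dt)
            bound = a_max * (g_max * dt) ** 2 / 8.0
            dlat = out_g[log.player_id]["lat"] - out_f[log.player_id]["lat"]
            dlon = out_g[log.player_id]["lon"] - out_f[log.player_id]["lon"]
            # convert degree errors to metres at this latitude
            err_m = np.hypot(dlat * 111_132.0, dlon * 111_320.0 * np.cos(np.radians(41.55)))
            rms = np.sqrt(np.mean(err_m**2))
            assert rms < bound


class TestRotation:
    def _rect(self, theta_deg, center=(0.0, 0.0)):
        hl, hw = 52.5, 34.0
        corners = np.array([[-hl, -hw], [hl, -hw], [hl, hw], [-hl, hw]])
        th = np.radians(theta_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return corners @ rot.T + np.asarray(center)

    def test_axis_aligned_rectangle_has_theta_zero(self):
        assert fit_rotation(self._rect(0.0)) == pytest.approx(0.0, abs=1e-9)

    def test_rotated_rectangle_recovers_angle(self):
        assert fit_rotation(self._rect(30.0)) == pytest.approx(30.0, abs=1e-9)

    def test_500_random_rotations_recovered_within_microdegrees(self, rng):
        for _ in range(500):
            theta = rng.uniform(0.0, 180.0)
            center = rng.uniform(-1000, 1000, 2)
            got = fit_rotation(self._rect(theta, center))
            diff = abs(got - theta) % 180.0
            assert min(diff, 180.0 - diff) < 1e-6

    def test_degenerate_vertices_raise(self):
        line = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        with pytest.raises(ValueError, match="degenerate"):
            fit_rotation(line)

    def test_non_rectangle_warns(self):
        quad = np.array([[0.0, 0.0], [100.0, 0.0], [100.0, 60.0], [-20.0, 70.0]])
        with pytest.warns(UserWarning, match="5%"):
            fit_rotation(quad)

    def test_apply_rotation_identity_and_quarter_turn(self):
        pts = np.array([[1.0, 0.0], [0.0, 0.0], [-1.0, 0.0]])
        assert np.allclose(apply_rotation(pts, 0.0), pts)
        out = apply_rotation(pts, 90.0, center=np.zeros(2))
        assert np.allclose(out[0], [0.0, -1.0], atol=1e-12)

    def test_apply_rotation_preserves_pairwise_distances(self, rng):
        pts = rng.uniform(-100, 100, size=(40, 2))
        out = apply_rotation(pts, rng.uniform(0, 360))
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d1 = np.linalg.norm(out[:, None] - out[None, :], axis=-1)
        assert np.max(np.abs(d0 - d1)) < 1e-9


class TestLowpass:
    def test_constant_series_unchanged(self):
        x = np.full(500, 3.7)
        assert np.max(np.abs(lowpass_smooth(x, 2.0, 5.0) - x)) < 1e-9

    def test_low_frequency_amplitude_preserved(self):
        t = np.arange(0, 600, 0.2)
        x = np.sin(2 * np.pi * 0.1 * t)
        y = lowpass_smooth(x, 3.0, 5.0)  # clamps to 2.475 Hz
        mid = slice(500, -500)
        assert np.max(np.abs(y[mid])) == pytest.approx(1.0, rel=0.01)

    def test_attenuation_matches_dual_pass_transfer_function(self):
        # |H(f)|^2 of the 2nd-order Butterworth applied forward-backward
        f0, rate = 2.4, 5.0
        t = np.arange(0, 600, 1 / rate)
        x = np.sin(2 * np.pi * f0 * t)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            y = lowpass_smooth(x, 3.0, rate)
        b, a = signal.butter(2, (0.99 * rate / 2) / (rate / 2))
        _, h = signal.freqz(b, a, worN=[f0], fs=rate)
        expected = np.abs(h[0]) ** 2
        mid = slice(1000, -1000)
        achieved = np.max(np.abs(y[mid]))
        assert achieved == pytest.approx(expected, rel=0.05)

    def test_cutoff_above_nyquist_warns_and_clamps(self):
        x = np.sin(np.arange(200) * 0.3)
        with pytest.warns(UserWarning, match="Nyquist"):
            lowpass_smooth(x, 3.0, 5.0)

    def test_short_series_raises(self):
        with pytest.raises(ValueError, match="warm-up"):
            lowpass_smooth(np.arange(5.0), 1.0, 5.0)


class TestFullChain:
    def test_straight_track_path_length_preserved(self):
        t = np.arange(0, 120, 0.2)
        x = 1.5 * t - 90.0  # 1.5 m/s along the pitch
        y = 0.05 * t
        cfg = SimulationConfig(duration=2.0, field_rotation_deg=35.0)
        vertices = generate_field_vertices(cfg)
        th = np.radians(35.0)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        e0, n0, zone = latlon_to_utm(cfg.field_origin_lat, cfg.field_origin_lon)
        enu = np.column_stack([x, y]) @ rot.T + [e0, n0]
        lat, lon = utm_to_latlon(enu[:, 0], enu[:, 1], zone)
        log = RawPositionLog(player_id="A", times=t, lat=lat, lon=lon)
        trajs, geom = preprocess_match([log], vertices, rate=5.0)
        tr = trajs["A"]
        path = np.sum(np.hypot(np.diff(tr.x), np.diff(tr.y)))
        expected = np.sum(np.hypot(np.diff(x), np.diff(y)))
        assert path == pytest.approx(expected, rel=5e-3)

    def test_pipeline_deterministic(self, short_config):
        logs, _ = generate_match(short_config, "amateur")
        vertices = generate_field_vertices(short_config)
        t1, _ = preprocess_match(logs, vertices)
        t2, _ = preprocess_match(logs, vertices)
        for pid in t1:
            assert t1[pid].x.tobytes() == t2[pid].x.tobytes()
            assert t1[pid].y.tobytes() == t2[pid].y.tobytes()

    def test_round_trip_recovers_generator_coordinates(self, quiet_config):
        # noise-free generator -> lat/lon -> preprocessing (no smoothing)
        # must recover the analytic pitch-frame path up to a global sign
        cfg = replace(quiet_config, field_rotation_deg=63.0)
        logs, truth = generate_match(cfg, "first_league")
        vertices = generate_field_vertices(cfg)
        trajs, geom = preprocess_match(logs, vertices, smooth=False)
        t = np.arange(cfg.n_samples) / cfg.sample_rate
        om_x = 2 * np.pi / cfg.base_period_x
        om_y = 2 * np.pi / cfg.base_period_y
        for pid, tr in trajs.items():
            ax, ay = truth.anchors[pid]
            phx = np.radians(truth.player_offsets_deg["x"][pid])
            phy = np.radians(truth.player_offsets_deg["y"][pid])
            x_true = ax + cfg.osc_amp_x * np.sin(om_x * t + phx)
            y_true = ay + cfg.osc_amp_y * np.sin(om_y * t + phy)
            err_pos = max(np.max(np.abs(tr.x - x_true)), np.max(np.abs(tr.y - y_true)))
            err_neg = max(np.max(np.abs(tr.x + x_true)), np.max(np.abs(tr.y + y_true)))
            assert min(err_pos, err_neg) < 1e-6
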