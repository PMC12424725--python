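"""Tracking, velocities, phase binning, polar decomposition, CV curves."""

import numpy as np
import pandas as pd
import pytest

import loopscope.analysis as ana
from loopscope.patterns import BarWaveParams


def _frames_from_positions(positions_by_time):
    return [
        pd.DataFrame({"time_s": t, "x_um": xy[:, 0], "y_um": xy[:, 1]})
        for t, xy in positions_by_time
    ]


class TestLinkTracks:
    def test_stationary_cells_one_track_each(self):
        xy = np.array([[10.0, 10.0], [50.0, 50.0]])
        frames = _frames_from_positions([(i * 300.0, xy) for i in range(5)])
        tracks = ana.link_tracks(frames, max_link_distance_um=10.0)
        assert len(tracks) == 2
        assert all(len(t) == 5 for t in tracks)

    def test_distance_gate_prevents_false_links(self):
        # both cells jump far beyond the gate in one step
        a = np.array([[0.0, 0.0], [100.0, 0.0]])
        b = np.array([[200.0, 0.0], [300.0, 0.0]])
        tracks = ana.link_tracks(_frames_from_positions([(0.0, a), (300.0, b)]), 10.0)
        assert len(tracks) == 4
        assert all(len(t) == 1 for t in tracks)

    def test_recovers_identity_on_simulated_drift(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 400, (80, 2))  # spacing >> displacement
        frames = []
        for i in range(10):
            drift = np.array([0.4, 0.8]) * i
            noisy = xy + drift + rng.normal(0, 0.2, xy.shape)
            df = pd.DataFrame(
                {"time_s": i * 300.0, "x_um": noisy[:, 0], "y_um": noisy[:, 1], "true_id": np.arange(80)}
            )
            frames.append(df)
        tracks = ana.link_tracks(frames, max_link_distance_um=10.0)
        full = [t for t in tracks if len(t) == 10]
        correct = sum(1 for t in full if t.samples["true_id"].nunique() == 1)
        assert correct / 80 >= 0.99


class TestFrameVelocities:
    def test_constant_drift_velocity(self):
        # +10 um per 5-min frame in y -> 120 um/h
        frames = _frames_from_positions(
            [(i * 300.0, np.array([[5.0, 10.0 * i]])) for i in range(6)]
        )
        tracks = ana.link_tracks(frames, max_link_distance_um=50.0)
        v = ana.frame_velocities(tracks)
        assert np.allclose(v["vy"], 120.0)
        assert np.allclose(v["vx"], 0.0)

    def test_stationary_zero(self):
        frames = _frames_from_positions([(i * 60.0, np.array([[1.0, 2.0]])) for i in range(4)])
        v = ana.frame_velocities(ana.link_tracks(frames, 5.0))
        assert np.allclose(v[["vx", "vy"]], 0.0)

    def test_imposed_drift_recovered_within_5pct(self):
        rng = np.random.default_rng(1)
        xy0 = rng.uniform(50, 350, (60, 2))
        drift = np.array([3.0, -7.0])  # um/h
        frames = []
        for i in range(20):
            xy = xy0 + drift * (i * 300.0 / 3600.0) + rng.normal(0, 0.1, xy0.shape)
            frames.append(pd.DataFrame({"time_s": i * 300.0, "x_um": xy[:, 0], "y_um": xy[:, 1]}))
        v = ana.frame_velocities(ana.link_tracks(frames, 10.0))
        assert v["vx"].mean() == pytest.approx(3.0, rel=0.05)
        assert v["vy"].mean() == pytest.approx(-7.0, rel=0.05)


class TestVelocityVsPhase:
    P = BarWaveParams(period_um=100.0, speed_um_per_h=12.0, duty=0.5)

    def test_uniform_velocity_all_bins_equal(self):
        rng = np.random.default_rng(2)
        s = pd.DataFrame(
            {
                "time_s": rng.uniform(0, 57600, 5000),
                "y_um": rng.uniform(0, 1000, 5000),
                "vx": 0.0,
                "vy": 4.2,
            }
        )
        out = ana.velocity_vs_phase(s, self.P, n_bins=10)
        assert np.allclose(out["mean"].dropna(), 4.2)

    def test_hand_built_binning(self):
        # phases chosen in two bins of a 2-bin partition: [-0.5,0) and [0,0.5)
        p = BarWaveParams(period_um=100.0, speed_um_per_h=0.0, duty=0.5)
        c = 25.0  # bar center at t=0
        s = pd.DataFrame(
            {
                "time_s": 0.0,
                "y_um": [c - 30, c - 10, c + 10, c + 20, c + 40, c - 45],
                "vx": 0.0,
                "vy": [1.0, 3.0, 5.0, 7.0, 9.0, 11.0],
            }
        )
        out = ana.velocity_vs_phase(s, p, n_bins=2)
        assert out.loc[0, "mean"] == pytest.approx((1.0 + 3.0 + 11.0) / 3)
        assert out.loc[1, "mean"] == pytest.approx((5.0 + 7.0 + 9.0) / 3)
        assert out["count"].sum() == 6

    def test_empty_bins_flagged_not_zero(self):
        s = pd.DataFrame({"time_s": [0.0], "y_um": [25.0], "vx": [0.0], "vy": [1.0]})
        out = ana.velocity_vs_phase(s, self.P, n_bins=10)
        assert out["count"].sum() == 1
        assert out["mean"].isna().sum() == 9

    def test_replicate_aggregation(self):
        s = pd.DataFrame(
            {
                "time_s": 0.0,
                "y_um": [25.0] * 4,  # all at phase 0
                "vx": 0.0,
                "vy": [1.0, 1.0, 3.0, 3.0],
                "rep": ["a", "a", "b", "b"],
            }
        )
        p = BarWaveParams(period_um=100.0, speed_um_per_h=0.0, duty=0.5)
        out = ana.velocity_vs_phase(s, p, n_bins=2, replicate_col="rep")
        row = out.dropna(subset=["mean"]).iloc[0]
        assert row["mean"] == pytest.approx(2.0)  # mean of replicate means
        assert row["sd"] == pytest.approx(np.std([1.0, 3.0], ddof=1))


class TestPhaseAligned:
    def test_track_at_center_aligns_to_frame_time(self):
        p = BarWaveParams(period_um=100.0, speed_um_per_h=12.0, duty=0.5)
        # cell sits where the bar center will be at t = 1800 s
        y_star = p.duty * p.period_um / 2 + 12.0 * 1800 / 3600
        frames = _frames_from_positions(
            [(t, np.array([[0.0, y_star]])) for t in (0.0, 900.0, 1800.0, 2700.0)]
        )
        tracks = ana.link_tracks(frames, 5.0)
        traces, mean_trace, excluded = ana.phase_aligned_traces(tracks, p)
        assert excluded == 0
        tr = traces[0]
        assert tr.loc[tr["dt_s"] == 0.0].shape[0] == 1 or abs(tr["dt_s"]).min() < 900

    def test_never_crossing_excluded_and_counted(self):
        p = BarWaveParams(period_um=1000.0, speed_um_per_h=1.0, duty=0.5)
        frames = _frames_from_positions([(t, np.array([[0.0, 900.0]])) for t in (0.0, 300.0)])
        tracks = ana.link_tracks(frames, 5.0)
        traces, _, excluded = ana.phase_aligned_traces(tracks, p)
        assert traces == [] and excluded == 1

    def test_identical_tracks_mean_equals_single(self):
        p = BarWaveParams(period_um=100.0, speed_um_per_h=12.0, duty=0.5)
        xy = np.array([[0.0, 30.0], [500.0, 30.0]])  # same y: identical traces
        frames = _frames_from_positions([(t, xy + [0, 2 * t / 3600]) for t in np.arange(6) * 600.0])
        tracks = ana.link_tracks(frames, 10.0)
        traces, mean_trace, _ = ana.phase_aligned_traces(tracks, p)
        assert len(traces) == 2
        merged = pd.concat(traces)
        per_dt = merged.groupby(merged["dt_s"].round(6))["disp_um"].std()
        assert (per_dt.fillna(0.0) < 1e-9).all()


class TestPolar:
    def _rotation_samples(self, omega_per_h=0.5, n=500, seed=3):
        rng = np.random.default_rng(seed)
        r = rng.uniform(10, 200, n)
        th = rng.uniform(0, 2 * np.pi, n)
        x, y = r * np.cos(th), r * np.sin(th)
        # ccw on screen (y down): tangent = (ry, -rx)/r
        vx, vy = omega_per_h * y, -omega_per_h * x
        return pd.DataFrame({"x_um": x, "y_um": y, "vx": vx, "vy": vy, "time_s": 0.0})

    def test_pure_rotation_no_radial(self):
        s = ana.polar_decompose(self._rotation_samples(), (0.0, 0.0))
        assert np.allclose(s["v_radial"], 0.0, atol=1e-9)
        assert (s["v_tangential"] > 0).all()

    def test_pure_expansion_no_tangential(self):
        s = self._rotation_samples()
        s[["vx", "vy"]] = s[["x_um", "y_um"]].to_numpy() * 0.1
        out = ana.polar_decompose(s, (0.0, 0.0))
        assert np.allclose(out["v_tangential"], 0.0, atol=1e-9)
        assert (out["v_radial"] > 0).all()

    def test_speed_preserved(self):
        s = self._rotation_samples()
        s["vx"] += 1.3
        out = ana.polar_decompose(s, (0.0, 0.0))
        lhs = out["v_radial"] ** 2 + out["v_tangential"] ** 2
        rhs = out["vx"] ** 2 + out["vy"] ** 2
        assert np.allclose(lhs, rhs)

    def test_rigid_rotation_profile_linear_in_radius(self):
        s = self._rotation_samples(omega_per_h=0.5, n=4000)
        prof = ana.radial_profile(s, (0.0, 0.0), n_rings=5, r_max_um=200.0)
        assert not prof["empty"].any()
        assert np.allclose(prof["omega_mean"], 0.5, rtol=0.01)
        vt = prof["v_tangential_mean"].to_numpy()
        assert (np.diff(vt) > 0).all()  # faster movement far from the origin

    def test_hand_built_three_rings(self):
        s = pd.DataFrame(
            {
                "x_um": [10.0, 0.0, 50.0, 0.0, 89.0],
                "y_um": [0.0, -20.0, 0.0, 55.0, 0.0],
                "vx": [0.0, -2.0, 0.0, 3.0, 0.0],
                "vy": [-1.0, 0.0, -2.0, 0.0, -3.0],
            }
        )
        out = ana.radial_profile(s, (0.0, 0.0), n_rings=3, r_max_um=90.0)
        # ring 0 (0-30): r=10 vt=1; r=20 vt=2 -> mean 1.5
        assert out.loc[0, "v_tangential_mean"] == pytest.approx(1.5)
        assert out.loc[1, "v_tangential_mean"] == pytest.approx((2.0 + 3.0) / 2)
        assert out.loc[2, "count"] == 1


class TestCvTimecourse:
    def test_equal_intensities_zero_cv(self):
        cells = pd.DataFrame({"time_s": [0.0] * 4, "mean_intensity": [5.0] * 4})
        out = ana.intensity_cv_timecourse(cells)
        assert out.loc[0, "cv"] == 0.0

    def test_hand_arithmetic(self):
        cells = pd.DataFrame({"time_s": [0.0, 0.0], "mean_intensity": [1.0, 3.0]})
        out = ana.intensity_cv_timecourse(cells)
        # sd(ddof=1)/mean = sqrt(2)/2
        assert out.loc[0, "cv"] == pytest.approx(np.sqrt(2.0) / 2.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        base = pd.DataFrame(
            {
                "time_s": np.repeat([0.0, 60.0, 120.0], 50),
                "mean_intensity": rng.lognormal(0, 0.4, 150),
            }
        )
        scaled = base.assign(mean_intensity=base["mean_intensity"] * 7.3)
        a = ana.intensity_cv_timecourse(base)["cv"]
        b = ana.intensity_cv_timecourse(scaled)["cv"]
        assert np.allclose(a, b)

    def test_fold_reduction_column(self):
        cells = pd.DataFrame(
            {
                "time_s": [0.0, 0.0, 60.0, 60.0],
                "mean_intensity": [1.0, 3.0, 1.9, 2.1],
            }
        )
        out = ana.intensity_cv_timecourse(cells)
        assert out.loc[0, "fold_reduction"] == pytest.approx(1.0)
        assert out.loc[1, "fold_reduction"] > 5.0

    def test_histograms_conserve_counts(self):
        cells = pd.DataFrame({"time_s": [0.0] * 10, "mean_intensity": np.linspace(0.5, 9.5, 10)})
        h = ana.intensity_histograms(cells, [0.0], np.arange(0.0, 11.0, 1.0))
        assert h["count"].sum() == 10
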