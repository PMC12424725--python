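"""Pattern engine: bars, wave phase, Voronoi, vortex, bang-bang, manager.

The bar/phase and Voronoi operations are checked against independent
brute-force oracles rather than against their own formulas.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import loopscope as ls
from loopscope.patterns import PatternManager
from loopscope.segmentation import CellObservation


def brute_force_bar_row(y, t, p):
    """Independent per-row evaluation: is physical coordinate y lit at time t?"""
    a = y - p.offset_um - p.speed_um_per_h * t / 3600.0
    return (a % p.period_um) < p.duty * p.period_um


def brute_force_phase(y, t, p):
    """Signed distance to the nearest enumerated bar center, in cycles."""
    travel = p.offset_um + p.speed_um_per_h * t / 3600.0 + p.duty * p.period_um / 2.0
    k0 = round((y - travel) / p.period_um)
    centers = [travel + k * p.period_um for k in range(int(k0) - 2, int(k0) + 3)]
    d = min((y - c for c in centers), key=abs)
    frac = d / p.period_um
    if frac >= 0.5:
        frac -= 1.0
    if frac < -0.5:
        frac += 1.0
    return frac if p.speed_um_per_h >= 0 else -frac


class TestBarWave:
    def test_matches_brute_force_on_random_params(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = ls.BarWaveParams(
                period_um=rng.uniform(20, 400),
                speed_um_per_h=rng.uniform(-60, 60),
                duty=rng.uniform(0.05, 1.0),
                offset_um=rng.uniform(-500, 500),
            )
            t = rng.uniform(0, 16 * 3600)
            px = rng.uniform(0.3, 2.0)
            pat = ls.bar_wave_pattern(p, t, px, (64, 3))
            expected = np.array([brute_force_bar_row(r * px, t, p) for r in range(64)])
            assert np.array_equal(pat.intensity[:, 0] > 0.5, expected)
            assert np.all(pat.intensity == pat.intensity[:, :1])  # constant along x

    def test_duty_one_always_lit(self):
        p = ls.BarWaveParams(period_um=100, speed_um_per_h=30, duty=1.0)
        for t in (0.0, 1234.0, 9999.0):
            assert ls.bar_wave_pattern(p, t, 1.0, (50, 2)).intensity.min() == 1.0

    def test_illuminated_fraction_equals_duty(self):
        rng = np.random.default_rng(1)
        rows = 512
        for _ in range(50):
            p = ls.BarWaveParams(
                period_um=rng.uniform(30, 200), speed_um_per_h=rng.uniform(0, 60), duty=rng.uniform(0.1, 0.9)
            )
            pat = ls.bar_wave_pattern(p, rng.uniform(0, 57600), 1.0, (rows, 1))
            assert abs(pat.intensity.mean() - p.duty) <= p.period_um / rows + 1.0 / rows

    def test_front_advances_at_wave_speed(self):
        for v in (12.0, 50.0):
            p = ls.BarWaveParams(period_um=400, speed_um_per_h=v, duty=0.25)
            a = ls.bar_wave_pattern(p, 0.0, 1.0, (400, 1)).intensity[:, 0]
            b = ls.bar_wave_pattern(p, 3600.0, 1.0, (400, 1)).intensity[:, 0]
            # leading edge = last lit row of the first bar
            front_a = np.nonzero(a)[0].min()  # bar starts at row 0 (offset 0)
            front_b = np.nonzero(b)[0].min()
            assert front_b - front_a == pytest.approx(v, abs=1.0)


class TestWavePhase:
    def test_zero_at_bar_center(self):
        p = ls.BarWaveParams(period_um=100, speed_um_per_h=12, duty=0.5)
        for t in (0.0, 600.0, 7200.0):
            c = p.offset_um + p.speed_um_per_h * t / 3600 + p.duty * p.period_um / 2
            assert ls.wave_phase(c, t, p) == pytest.approx(0.0, abs=1e-12)

    def test_wrap_boundary(self):
        p = ls.BarWaveParams(period_um=100, speed_um_per_h=0, duty=0.5, offset_um=0.0)
        eps = 1e-6
        c = p.duty * p.period_um / 2
        assert ls.wave_phase(c + 50 - eps, 0, p) == pytest.approx(0.5 - eps / 100, abs=1e-9)
        assert ls.wave_phase(c + 50.0, 0, p) == -0.5

    def test_matches_enumerated_center_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            p = ls.BarWaveParams(
                period_um=rng.uniform(20, 300),
                speed_um_per_h=rng.uniform(-60, 60),
                duty=rng.uniform(0.05, 1.0),
                offset_um=rng.uniform(-300, 300),
            )
            y, t = rng.uniform(-1000, 1000), rng.uniform(0, 57600)
            assert ls.wave_phase(y, t, p) == pytest.approx(brute_force_phase(y, t, p), abs=1e-9)

    def test_pixel_lit_iff_phase_in_duty_window(self):
        """Cross-module identity: illumination <=> phase in [-d/2, d/2)."""
        rng = np.random.default_rng(3)
        for _ in range(30):
            p = ls.BarWaveParams(
                period_um=rng.uniform(30, 200),
                speed_um_per_h=rng.uniform(0, 60),
                duty=rng.uniform(0.1, 0.9),
                offset_um=rng.uniform(0, 100),
            )
            t = rng.uniform(0, 57600)
            pat = ls.bar_wave_pattern(p, t, 1.0, (256, 1))
            phases = ls.wave_phase(np.arange(256, dtype=float), t, p)
            lit = pat.intensity[:, 0] > 0.5
            in_window = (phases >= -p.duty / 2) & (phases < p.duty / 2)
            assert np.array_equal(lit, in_window)


class TestVoronoi:
    def test_single_centroid_owns_fov(self):
        m = ls.voronoi_assign([(7, 3.0, 4.0)], (16, 16))
        assert np.all(m == 7)

    def test_tie_goes_to_smaller_label(self):
        m = ls.voronoi_assign([(1, 0.0, 5.0), (2, 10.0, 5.0)], (11, 11))
        assert np.all(m[:, 5] == 1)  # equidistant column
        assert np.all(m[:, :5] == 1) and np.all(m[:, 6:] == 2)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            rows = int(rng.integers(16, 129))
            cols = int(rng.integers(16, 129))
            n = int(rng.integers(1, 65))
            labels = rng.permutation(1000)[:n] + 1
            pts = np.column_stack(
                [rng.uniform(0, cols - 1, n), rng.uniform(0, rows - 1, n)]
            )
            cents = [(int(lab), float(x), float(y)) for lab, (x, y) in zip(labels, pts)]
            got = ls.voronoi_assign(cents, (rows, cols))
            yy, xx = np.mgrid[0:rows, 0:cols]
            d2 = (xx[..., None] - pts[:, 0]) ** 2 + (yy[..., None] - pts[:, 1]) ** 2
            order = np.argsort(labels)  # smaller label wins ties
            d2s = d2[..., order]
            expected = np.sort(labels)[np.argmin(d2s, axis=-1)]
            assert np.array_equal(got, expected)

    def test_empty_rejected(self):
        with pytest.raises(ls.LoopscopeError):
            ls.voronoi_assign([], (8, 8))


def _square_region(label, fov):
    return np.full(fov, label, dtype=int)


class TestVortex:
    def test_ramp_increases_along_tangent_constant_along_radius(self):
        # single off-center cell owning the full (square) FOV
        cents = [(1, 20.0, 12.0)]
        regions = _square_region(1, (25, 41))
        p = ls.VortexParams(center=(20.0, 24.0), chirality="ccw")
        pat = ls.vortex_gradient_pattern(cents, regions, p).intensity
        # r = (0, -12) => ccw tangent (ry, -rx)/|r| = (-1, 0): brightest at small x
        assert np.all(np.diff(pat[12, :]) <= 1e-12)
        assert pat[12, 0] == pytest.approx(1.0)
        # constant along the radial (y) direction
        assert np.allclose(pat[:, 5], pat[12, 5])

    def test_chirality_mirror(self):
        cents = [(1, 30.0, 10.0)]
        regions = _square_region(1, (21, 61))
        ccw = ls.vortex_gradient_pattern(cents, regions, ls.VortexParams(center=(30.0, 18.0), chirality="ccw"))
        cw = ls.vortex_gradient_pattern(cents, regions, ls.VortexParams(center=(30.0, 18.0), chirality="cw"))
        assert np.allclose(ccw.intensity, cw.intensity[:, ::-1])

    def test_center_cell_uniform_half_power(self):
        cents = [(1, 8.0, 8.0)]
        regions = _square_region(1, (17, 17))
        pat = ls.vortex_gradient_pattern(cents, regions, ls.VortexParams(center=(8.0, 8.0)))
        assert np.allclose(pat.intensity, 0.5)


def _obs(label, mean, channel="fluor"):
    return CellObservation(label=label, centroid=(0.0, 0.0), area=1, mean_intensity={channel: mean})


class TestBangBang:
    def test_all_above_setpoint_dark(self):
        mask = np.array([[1, 1], [2, 2]])
        p = ls.BangBangParams(setpoint=10.0)
        pat = ls.bang_bang_pattern([_obs(1, 12.0), _obs(2, 11.0)], mask, p)
        assert pat.intensity.max() == 0.0

    def test_below_setpoint_fully_lit(self):
        mask = np.array([[1, 1], [2, 2]])
        pat = ls.bang_bang_pattern([_obs(1, 10.0), _obs(2, 25.0)], mask, ls.BangBangParams(setpoint=20.0))
        assert np.all(pat.intensity[0] == 1.0) and np.all(pat.intensity[1] == 0.0)

    def test_setpoint_image_sampled_over_mask(self):
        mask = np.array([[1, 1], [2, 2]])
        sp = np.array([[30.0, 10.0], [5.0, 5.0]])  # cell 1 mean set point 20
        pat = ls.bang_bang_pattern([_obs(1, 19.0), _obs(2, 19.0)], mask, ls.BangBangParams(setpoint=sp))
        assert np.all(pat.intensity[0] == 1.0) and np.all(pat.intensity[1] == 0.0)

    def test_setpoint_image_shape_mismatch(self):
        with pytest.raises(ls.LoopscopeError, match="shape"):
            ls.bang_bang_pattern([_obs(1, 1.0)], np.ones((2, 2), int), ls.BangBangParams(setpoint=np.ones((3, 3))))

    def test_idempotent_at_fixed_measurements(self):
        mask = (np.arange(36) % 4).reshape(6, 6)
        obs = [_obs(1, 5.0), _obs(2, 50.0), _obs(3, 7.0)]
        p = ls.BangBangParams(setpoint=10.0)
        a = ls.bang_bang_pattern(obs, mask, p).intensity
        b = ls.bang_bang_pattern(obs, mask, p).intensity
        assert np.array_equal(a, b)
        assert set(np.unique(a)) <= {0.0, 1.0}


class TestConstantAndManager:
    def test_constant_full_and_empty(self):
        assert ls.constant_pattern((8, 8), 1.0).intensity.min() == 1.0
        assert ls.constant_pattern((8, 8), 1.0, region=(2, 2, 2, 5)).intensity.max() == 0.0

    def test_constant_rectangle(self):
        pat = ls.constant_pattern((8, 8), 0.5, region=(1, 2, 4, 6)).intensity
        assert pat[2:6, 1:4].min() == 0.5 and pat.sum() == 0.5 * 3 * 4

    def test_manager_serves_latest_valid(self):
        mgr = PatternManager(fov_shapes={"A": (4, 4)})
        p0 = ls.StimulusPattern(np.zeros((4, 4)), valid_from=0.0, position_name="A")
        p300 = ls.StimulusPattern(np.ones((4, 4)), valid_from=300.0, position_name="A")
        mgr.submit(p0)
        mgr.submit(p300)
        assert mgr.current("A", 200.0) is p0
        assert mgr.current("A", 300.0) is p300

    def test_manager_dark_fallback(self):
        mgr = PatternManager(fov_shapes={"A": (4, 4)})
        pat = mgr.current("A", 10.0)
        assert pat.intensity.max() == 0.0 and pat.provenance == "fallback-dark"

    def test_manager_parametric_equals_direct_calls(self):
        p = ls.BarWaveParams(period_um=100, speed_um_per_h=12, duty=0.5)
        mgr = PatternManager(fov_shapes={"A": (32, 4)})
        mgr.register_parametric("A", lambda t: ls.bar_wave_pattern(p, t, 1.0, (32, 4)))
        for t in (60.0, 120.0, 3600.0):
            direct = ls.bar_wave_pattern(p, t, 1.0, (32, 4)).intensity
            assert np.array_equal(mgr.current("A", t).intensity, direct)


@given(
    period=st.floats(10, 500),
    speed=st.floats(-100, 100),
    duty=st.floats(0.01, 1.0),
    t=st.floats(0, 57600),
)
@settings(max_examples=60, deadline=None)
def test_patterns_stay_in_unit_range_and_binary(period, speed, duty, t):
    p = ls.BarWaveParams(period_um=period, speed_um_per_h=speed, duty=duty)
    img = ls.bar_wave_pattern(p, t, 1.0, (32, 2)).intensity
    assert set(np.unique(img)) <= {0.0, 1.0}
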