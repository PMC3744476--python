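"""Dispersion and occupancy statistics against closed forms and brute force."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fairycircles.geometry import CirclePattern, SpatialWindow, hexagonal_window
from fairycircles.patterns import gen_csr, gen_hexagonal
from fairycircles.spatial import (
    clark_evans,
    cumulative_circumference,
    landscape_occupancy,
    nn_distances,
    periphery_distances,
    summarize_patterns,
)


def brute_force_nn(pts: np.ndarray, window: SpatialWindow, mode: str) -> np.ndarray:
    """O(n^2) oracle; toroidal distances via the minimum-image convention."""
    n = len(pts)
    out = np.empty(n)
    for i in range(n):
        d = pts - pts[i]
        if mode == "toroidal":
            for k, span in enumerate((window.width, window.height)):
                d[:, k] = np.where(np.abs(d[:, k]) > span / 2, span - np.abs(d[:, k]), np.abs(d[:, k]))
        dist = np.hypot(d[:, 0], d[:, 1])
        dist[i] = np.inf
        out[i] = dist.min()
    return out


class TestNNDistances:
    def test_two_points_both_report_their_separation(self, window100):
        pts = np.array([[10.0, 10.0], [13.0, 14.0]])
        np.testing.assert_allclose(nn_distances(pts, window100), [5.0, 5.0])

    def test_square_lattice_toroidal(self):
        w = SpatialWindow(0, 10, 0, 10, "toroidal")
        xs, ys = np.meshgrid(np.arange(10) + 0.5, np.arange(10) + 0.5)
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        np.testing.assert_allclose(nn_distances(pts, w), 1.0)

    def test_single_point_rejected(self, window100):
        with pytest.raises(ValueError):
            nn_distances(np.array([[1.0, 1.0]]), window100)

    @pytest.mark.parametrize("mode", ["euclidean", "toroidal"])
    def test_matches_brute_force_oracle(self, mode, torus100, rng):
        for _ in range(200):
            n = rng.integers(2, 40)
            pts = rng.uniform(0, 100, (n, 2))
            fast = nn_distances(pts, torus100, mode)
            slow = brute_force_nn(pts.copy(), torus100, mode)
            np.testing.assert_allclose(fast, slow, rtol=1e-10)


class TestClarkEvans:
    def test_square_lattice_r_is_two(self):
        w = SpatialWindow(0, 20, 0, 20, "toroidal")
        xs, ys = np.meshgrid(np.arange(20) + 0.5, np.arange(20) + 0.5)
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        res = clark_evans(pts, w)
        # rho = 1, r_obs = 1, r_exp = 1/2 -> R = 2 exactly
        assert res.R == pytest.approx(2.0, abs=1e-12)

    def test_hexagonal_lattice_r_is_maximum(self):
        w = hexagonal_window(4.0, 20, 20)
        pat = gen_hexagonal(4.0, 0.0, w, seed=0)
        res = clark_evans(pat.centers, w)
        assert round(res.R, 2) == 2.15

    def test_z_zero_p_one_when_observed_equals_expected(self, torus100):
        # calibrate a two-point toy so r_obs == r_exp by construction
        w = SpatialWindow(0, 2, 0, 2)
        r_exp = 1.0 / (2.0 * np.sqrt(2 / 4))  # ~0.707
        pts = np.array([[0.5, 0.5], [0.5 + r_exp, 0.5]])
        res = clark_evans(pts, w)
        assert res.Z == pytest.approx(0.0, abs=1e-12)
        assert res.p_two_sided == pytest.approx(1.0)
        assert not res.significant_at_05

    @given(scale=st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=20, deadline=None)
    def test_r_and_z_are_scale_invariant(self, scale):
        w = SpatialWindow(0, 100, 0, 100, "toroidal")
        pts = gen_csr(60, w, seed=11).centers
        base = clark_evans(pts, w)
        w2 = SpatialWindow(0, 100 * scale, 0, 100 * scale, "toroidal")
        scaled = clark_evans(pts * scale, w2)
        assert scaled.R == pytest.approx(base.R, rel=1e-9)
        assert scaled.Z == pytest.approx(base.Z, rel=1e-9)


class TestOccupancy:
    def test_two_unit_circles_in_hundred_m2(self):
        w = SpatialWindow(0, 10, 0, 10)
        pat = CirclePattern([[3, 3], [7, 7]], [1.0, 1.0], w)
        assert landscape_occupancy(pat) == pytest.approx(2 * np.pi, rel=1e-12)

    def test_empty_pattern_zero(self, window100):
        pat = CirclePattern(np.empty((0, 2)), [], window100)
        assert landscape_occupancy(pat) == 0.0

    def test_field_scale_example(self):
        # 16 circles/ha of 23 m^2 -> 16*23/10000 = 3.68%
        w = SpatialWindow(0, 100, 0, 100)
        r = np.sqrt(23 / np.pi)
        xs, ys = np.meshgrid(np.arange(4) * 25 + 12.5, np.arange(4) * 25 + 12.5)
        pat = CirclePattern(np.column_stack([xs.ravel(), ys.ravel()]), np.full(16, r), w)
        assert landscape_occupancy(pat) == pytest.approx(3.68, rel=1e-9)


class TestPeripheryDistances:
    def test_center_distance_minus_radii(self, window100):
        pat = CirclePattern([[10, 10], [20, 10]], [2.0, 3.0], window100)
        np.testing.assert_allclose(periphery_distances(pat), [5.0, 5.0])

    def test_touching_circles_floor_at_zero(self, window100):
        pat = CirclePattern([[10, 10], [14, 10]], [2.0, 2.0], window100)
        np.testing.assert_allclose(periphery_distances(pat), [0.0, 0.0])

    def test_single_circle_rejected(self, window100):
        pat = CirclePattern([[10, 10]], [2.0], window100)
        with pytest.raises(ValueError):
            periphery_distances(pat)


class TestCumulativeCircumference:
    def test_one_unit_circle_per_hectare(self):
        w = SpatialWindow(0, 100, 0, 100)
        pat = CirclePattern([[50, 50]], [1.0], w)
        assert cumulative_circumference(pat) == pytest.approx(2 * np.pi, rel=1e-12)

    def test_empty_is_zero(self, window100):
        pat = CirclePattern(np.empty((0, 2)), [], window100)
        assert cumulative_circumference(pat) == 0.0

    def test_field_scale_example(self):
        # 16 circles/ha at 5 m diameter -> 16 * pi * 5 = 251.3 m/ha
        w = SpatialWindow(0, 100, 0, 100)
        xs, ys = np.meshgrid(np.arange(4) * 25 + 12.5, np.arange(4) * 25 + 12.5)
        pat = CirclePattern(np.column_stack([xs.ravel(), ys.ravel()]), np.full(16, 2.5), w)
        assert cumulative_circumference(pat) == pytest.approx(16 * np.pi * 5, rel=1e-12)


class TestSummarizePatterns:
    def test_single_circle_degenerate_summary(self):
        w = SpatialWindow(0, 100, 0, 100)
        pat = CirclePattern([[50, 50]], [2.4], w)
        s = summarize_patterns(pat)
        assert s.diameter_mean_m == s.diameter_median_m == s.diameter_p5_m == 4.8
        assert s.density_se is None and s.R_se is None  # no SE for one site

    def test_ensemble_reports_se_fields(self, torus100):
        pats = [
            CirclePattern(gen_csr(30, torus100, seed=s).centers, np.full(30, 2.4), torus100)
            for s in range(4)
        ]
        s = summarize_patterns(pats)
        assert s.n_sites == 4
        assert s.density_se is not None and s.density_se >= 0
        assert s.R_se is not None
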