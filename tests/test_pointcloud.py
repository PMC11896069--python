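"""Pre-processing: outlier removal, ground filtering, DTM, normalization."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from miombo_aba.pointcloud import (
    CLASS_GROUND,
    CLASS_NOISE,
    DTMRaster,
    PointCloud,
    build_dtm,
    classify_ground,
    denoise,
    normalize_heights,
    preprocess,
)
from miombo_aba.synthforest import SensorConfig, planar_terrain, simulate_point_cloud

from conftest import grid_cloud


def brute_force_noise_flags(cloud, k, mult):
    pts = np.column_stack([cloud.x, cloud.y, cloud.z])
    n = len(pts)
    md = np.empty(n)
    for i in range(n):
        d = np.sqrt(((pts - pts[i]) ** 2).sum(axis=1))
        md[i] = np.sort(d)[1 : k + 1].mean()
    return md > md.mean() + mult * md.std()


class TestDenoise:
    def test_single_outlier_flagged(self):
        cloud = grid_cloud(10, extra=(4.5, 4.5, 50.0))
        out = denoise(cloud, k_neighbors=4, std_multiplier=3.0)
        flagged = np.flatnonzero(out.classification == CLASS_NOISE)
        assert list(flagged) == [100]

    def test_matches_brute_force_oracle(self, rng):
        n = 200
        cloud = PointCloud(
            rng.uniform(0, 50, n), rng.uniform(0, 50, n), rng.uniform(0, 30, n),
            np.ones(n, dtype=int), np.ones(n, dtype=int),
        )
        out = denoise(cloud, k_neighbors=6, std_multiplier=2.0)
        expected = brute_force_noise_flags(cloud, 6, 2.0)
        np.testing.assert_array_equal(out.classification == CLASS_NOISE, expected)

    def test_homogeneous_grid_unflagged(self):
        # k=1: every nearest-neighbour distance identical, so zero spread
        out = denoise(grid_cloud(10), k_neighbors=1, std_multiplier=3.0)
        assert (out.classification != CLASS_NOISE).all()

    def test_idempotent_on_survivors(self):
        cloud = grid_cloud(10, extra=(4.5, 4.5, 50.0))
        once = denoise(cloud, k_neighbors=1, std_multiplier=3.0)
        survivors = once.without_noise()
        twice = denoise(survivors, k_neighbors=1, std_multiplier=3.0)
        assert (twice.classification != CLASS_NOISE).all()

    def test_contract_errors(self):
        cloud = grid_cloud(3)
        with pytest.raises(ValueError):
            denoise(cloud, k_neighbors=9)  # k >= n
        with pytest.raises(ValueError):
            denoise(cloud.select(np.zeros(9, dtype=bool)), 1, 3.0)  # empty

    def test_never_removes_much_on_clean_scene(self, small_scene):
        _, _, cloud, truth = small_scene
        out = denoise(cloud, k_neighbors=10, std_multiplier=3.0)
        frac = (out.classification == CLASS_NOISE).mean()
        injected = (truth["true_class"] == "outlier").mean()
        assert frac <= injected + 0.01


class TestClassifyGround:
    def test_pure_ground_cloud_all_ground(self):
        cloud = grid_cloud(12, spacing=2.0, z=100.0)
        out = classify_ground(cloud, grid_cell=10.0)
        assert (out.classification == CLASS_GROUND).all()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            classify_ground(grid_cloud(1))

    def test_flat_scene_recall_precision(self, small_scene):
        """Ground returns on a flat floor recovered against simulator truth."""
        _, _, cloud, truth = small_scene
        out = classify_ground(denoise(cloud, 10, 3.0), grid_cell=15.0)
        is_ground = out.classification == CLASS_GROUND
        true_ground = truth["true_class"].to_numpy() == "ground"
        recall = (is_ground & true_ground).sum() / true_ground.sum()
        precision = (is_ground & true_ground).sum() / max(is_ground.sum(), 1)
        assert recall >= 0.95
        assert precision >= 0.95

    def test_noise_points_ignored(self):
        cloud = grid_cloud(10, z=50.0, extra=(4.5, 4.5, 120.0))
        cls = cloud.classification.copy()
        cls[-1] = CLASS_NOISE
        cloud = PointCloud(cloud.x, cloud.y, cloud.z, cloud.return_number,
                           cloud.number_of_returns, cls)
        out = classify_ground(cloud, grid_cell=5.0)
        assert out.classification[-1] == CLASS_NOISE


class TestBuildDTM:
    def make_ground(self, x, y, z):
        n = len(x)
        ones = np.ones(n, dtype=int)
        return PointCloud(x, y, z, ones, ones,
                          np.full(n, CLASS_GROUND, dtype=np.int64))

    def test_constant_field(self):
        g = grid_cloud(10, z=100.0)
        cloud = self.make_ground(g.x, g.y, g.z)
        dtm = build_dtm(cloud, cell_size=2.0)
        np.testing.assert_allclose(dtm.values, 100.0)

    def test_two_point_hand_weights(self):
        """Cell centre equidistant from z=90 and z=110 -> exactly 100."""
        cloud = self.make_ground(np.array([0.0, 10.0]), np.array([0.0, 0.0]),
                                 np.array([90.0, 110.0]))
        dtm = build_dtm(cloud, cell_size=10.0, idw_power=2.0, n_neighbors=2,
                        bounds=(0.0, 0.0, 10.0, 1.0))
        assert dtm.values.shape == (1, 1)
        assert dtm.values[0, 0] == pytest.approx(100.0, abs=1e-12)

    def test_single_point_limit(self):
        cloud = self.make_ground(np.array([5.0]), np.array([5.0]), np.array([123.0]))
        dtm = build_dtm(cloud, cell_size=1.0, bounds=(0, 0, 10, 10))
        np.testing.assert_allclose(dtm.values, 123.0)

    def test_exact_hit_returns_point_z(self):
        cloud = self.make_ground(np.array([0.5, 3.0]), np.array([0.5, 3.0]),
                                 np.array([7.0, 9.0]))
        dtm = build_dtm(cloud, cell_size=1.0, bounds=(0, 0, 4, 4))
        assert dtm.values[0, 0] == 7.0  # centre (0.5, 0.5) coincides with the point

    def test_no_ground_rejected(self):
        g = grid_cloud(5)
        with pytest.raises(ValueError):
            build_dtm(g)

    def test_plane_reproduced_with_symmetric_neighbours(self):
        """Tilted-plane ground on a regular grid: cell centres sit at the centroid
        of their 4 nearest points, so IDW reproduces the plane exactly."""
        xs, ys = np.meshgrid(np.arange(21, dtype=float), np.arange(21, dtype=float))
        x, y = xs.ravel(), ys.ravel()
        z = 100.0 + 0.1 * x + 0.05 * y
        dtm = build_dtm(self.make_ground(x, y, z), cell_size=1.0, n_neighbors=4,
                        bounds=(0.0, 0.0, 20.0, 20.0))
        cx, cy = dtm.cell_centers()
        XX, YY = np.meshgrid(cx, cy)
        np.testing.assert_allclose(dtm.values, 100.0 + 0.1 * XX + 0.05 * YY,
                                   atol=1e-9)


class TestNormalize:
    def flat_dtm(self, value=100.0):
        return DTMRaster(0.0, 0.0, 1.0, np.full((10, 10), value))

    def test_subtraction(self):
        ones = np.ones(2, dtype=int)
        cloud = PointCloud([5.0, 5.0], [5.0, 5.0], [115.0, 99.8], ones, ones)
        out = normalize_heights(cloud, self.flat_dtm())
        assert out.z[0] == pytest.approx(15.0)
        assert out.z[1] == pytest.approx(-0.2)  # negative residual retained
        assert out.normalized

    def test_outside_coverage_rejected_with_cell(self):
        ones = np.ones(1, dtype=int)
        cloud = PointCloud([50.0], [5.0], [115.0], ones, ones)
        with pytest.raises(ValueError, match="cell index"):
            normalize_heights(cloud, self.flat_dtm())

    def test_bare_ground_pipeline_residuals(self):
        """On bare synthetic ground, mean |height| <= noise sd + DTM error."""
        terrain = planar_terrain((25, 25), slope_deg=3.0, base_elevation=500.0)
        sensor = SensorConfig(pulse_density=60.0, noise_sd=0.03,
                              outlier_fraction=0.0)
        import pandas as pd

        trees = pd.DataFrame(columns=["x", "y", "crown_radius", "height_m",
                                      "crown_depth"])
        cloud, _ = simulate_point_cloud(terrain, trees, sensor, seed=4)
        normalized, dtm = preprocess(cloud, denoise_k=8, ptin_cell=10.0)
        # tile edges carry one-sided IDW neighbourhoods; judge the interior
        interior = (
            (normalized.x > 2) & (normalized.x < 23)
            & (normalized.y > 2) & (normalized.y < 23)
        )
        h = np.abs(normalized.z[interior])
        assert np.mean(h) <= 0.03 + 0.05
        # 95th percentile of |height| within 2x (noise + interpolation error)
        assert np.percentile(h, 95) <= 2 * (0.03 + 0.05)


class TestAsciiRoundTrip:
    def test_roundtrip(self, tmp_path, rng):
        vals = rng.normal(1000, 5, (6, 4)).round(4)
        dtm = DTMRaster(10.0, 20.0, 2.0, vals)
        p = tmp_path / "dtm.asc"
        dtm.to_ascii(p)
        back = DTMRaster.from_ascii(p)
        assert back.x0 == 10.0 and back.y0 == 20.0 and back.cell_size == 2.0
        np.testing.assert_allclose(back.values, vals)
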