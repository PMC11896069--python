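import numpy as np
import pandas as pd
import pytest

from miombo_aba.pointcloud import PointCloud
from miombo_aba.synthforest import (
    SensorConfig,
    mwekera_like_config,
    planar_terrain,
    simulate_point_cloud,
    simulate_site,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def density_table():
    return pd.DataFrame(
        {
            "species": ["Julbernardia paniculata", "Brachystegia longifolia",
                        "Brachystegia spiciformis"],
            "genus": ["Julbernardia", "Brachystegia", "Brachystegia"],
            "density_g_cm3": [0.62, 0.50, 0.70],
        }
    )


@pytest.fixture(scope="session")
def small_scene():
    """One 30x30 m forested tile on a flat plane with exact truth labels."""
    from miombo_aba.synthforest import generate_stand

    terrain = planar_terrain((30.0, 30.0), slope_deg=0.0, base_elevation=1225.0)
    cfg = mwekera_like_config(seed=7)
    trees = generate_stand(terrain, cfg, seed=7)
    sensor = SensorConfig(pulse_density=80.0, noise_sd=0.02, outlier_fraction=0.002)
    cloud, truth = simulate_point_cloud(terrain, trees, sensor, seed=11)
    return terrain, trees, cloud, truth


@pytest.fixture(scope="session")
def tiny_site():
    """A 6-plot simulated site at low pulse density (shared, read-only)."""
    cfg = mwekera_like_config(seed=21)
    return simulate_site(cfg, SensorConfig(pulse_density=12.0), n_plots=6, seed=21)


def grid_cloud(n=10, spacing=1.0, z=0.0, extra=None):
    """Regular n x n grid of single returns at constant height."""
    xs, ys = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing)
    x = xs.ravel().astype(float)
    y = ys.ravel().astype(float)
    zz = np.full(x.size, float(z))
    if extra is not None:
        ex, ey, ez = extra
        x = np.append(x, ex)
        y = np.append(y, ey)
        zz = np.append(zz, ez)
    ones = np.ones(x.size, dtype=int)
    return PointCloud(x, y, zz, ones, ones)
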