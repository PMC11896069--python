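"""Synthetic Miombo-woodland stands and UAS-lidar point clouds.

The generator provides a fully self-contained test bed for the
area-based inventory pipeline: a smooth band-limited terrain surface, a
tree list drawn from a configurable species mixture whose diameter and
height structure mimics wet-Miombo summary statistics, and a triple-echo
lidar cloud at a configurable pulse density with Gaussian ranging noise
and a small fraction of gross outliers. True per-return labels (ground /
canopy / outlier) and the true terrain elevation under every return are
kept alongside the cloud so that ground filtering, DTM interpolation and
height normalization can be validated against exact truth.

Trees crowns are modelled as vertically stretched ellipsoids whose
radius grows allometrically with stem diameter; a pulse that hits one or
more crowns returns first from the highest crown envelope and penetrates
to the ground with a per-crown transmittance probability, yielding up to
three numbered echoes per pulse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .pointcloud import CLASS_UNCLASSIFIED, PointCloud

# ---------------------------------------------------------------------------
# Terrain


@dataclass
class TerrainModel:
    """Smooth synthetic terrain: a mean altitude plus band-limited relief.

    The surface is a sum of ``n_components`` sinusoids with random
    orientations and wavelengths; each contributes at most
    ``relief_amplitude / n_components`` so the total relief stays within
    +/- ``relief_amplitude`` of the base altitude (peak-to-peak range at
    most twice the amplitude).
    """

    origin: tuple[float, float]
    extent_x: float
    extent_y: float
    base_elevation: float
    relief_amplitude: float
    _amps: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    _freqs: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    _phases: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def elevation(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = np.full(np.broadcast(x, y).shape, self.base_elevation, dtype=float)
        if self.relief_amplitude > 0 and self._amps is not None:
            for a, (fx, fy), ph in zip(self._amps, self._freqs, self._phases):
                z = z + a * np.sin(2 * np.pi * (fx * x + fy * y) + ph)
        return z

    def contains(self, x, y) -> np.ndarray:
        x0, y0 = self.origin
        return (
            (np.asarray(x) >= x0)
            & (np.asarray(x) <= x0 + self.extent_x)
            & (np.asarray(y) >= y0)
            & (np.asarray(y) <= y0 + self.extent_y)
        )


def generate_terrain(
    extent: tuple[float, float],
    relief_amplitude: float = 5.0,
    seed: int = 0,
    origin: tuple[float, float] = (0.0, 0.0),
    base_elevation: float = 1225.0,
    n_components: int = 6,
    min_wavelength: float = 60.0,
) -> TerrainModel:
    """Generate a reproducible smooth terrain surface.

    ``min_wavelength`` (m) bounds the highest spatial frequency, keeping
    the surface band-limited (no relief features sharper than roughly
    half that scale).
    """
    ex, ey = float(extent[0]), float(extent[1])
    if ex <= 0 or ey <= 0:
        raise ValueError("terrain extent must be positive")
    if relief_amplitude < 0:
        raise ValueError("relief amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    wavelengths = rng.uniform(min_wavelength, 4 * min_wavelength, n_components)
    theta = rng.uniform(0, 2 * np.pi, n_components)
    freqs = np.column_stack([np.cos(theta), np.sin(theta)]) / wavelengths[:, None]
    phases = rng.uniform(0, 2 * np.pi, n_components)
    amps = np.full(n_components, relief_amplitude / n_components)
    return TerrainModel((origin[0], origin[1]), ex, ey, base_elevation, relief_amplitude,
                        amps, freqs, phases)


def planar_terrain(
    extent: tuple[float, float],
    slope_deg: float = 0.0,
    azimuth_deg: float = 0.0,
    base_elevation: float = 1225.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> TerrainModel:
    """A uniformly sloped plane, handy for controlled filter benchmarks."""
    t = TerrainModel((origin[0], origin[1]), float(extent[0]), float(extent[1]),
                     base_elevation, 0.0)
    if slope_deg != 0.0:
        g = math.tan(math.radians(slope_deg))
        az = math.radians(azimuth_deg)
        gx, gy = g * math.cos(az), g * math.sin(az)
        base = base_elevation
        x0, y0 = origin

        def elev(x, y, gx=gx, gy=gy, base=base, x0=x0, y0=y0):
            return base + gx * (np.asarray(x, dtype=float) - x0) + gy * (
                np.asarray(y, dtype=float) - y0
            )

        t.elevation = elev  # type: ignore[method-assign]
    return t


# ---------------------------------------------------------------------------
# Stand configuration

#: Representative genus-level wood densities (g/cm^3) for common wet-Miombo
#: taxa. Synthetic values typical of the genera, used only to parameterise
#: the generator and its tests.
WOOD_DENSITY_G_CM3: dict[str, float] = {
    "Julbernardia": 0.62,
    "Isoberlinia": 0.57,
    "Marquesia": 0.63,
    "Brachystegia": 0.55,
    "Parinari": 0.59,
    "Ochna": 0.68,
    "Baphia": 0.70,
    "Pericopsis": 0.72,
    "Diplorhynchus": 0.54,
    "Pseudolachnostylis": 0.66,
    "Combretum": 0.69,
}


@dataclass
class SpeciesParams:
    """One mixture component of a stand: a species with its DBH model."""

    species: str
    genus: str
    abundance: float  # relative, normalised across the mixture
    wood_density: float  # g/cm^3
    dbh_mean: float  # cm, arithmetic mean of the species' diameters
    dbh_sigma_ln: float  # log-scale spread of the lognormal DBH model
    dbh_max: float = 120.0  # cm, upper truncation of the lognormal draw


@dataclass
class StandConfig:
    """Everything needed to draw a tree list for one site."""

    site: str
    stem_density: float  # stems/ha
    species_mix: list[SpeciesParams]
    height_c0: float  # ln(H) = c0 + c1 ln(D) + N(0, sigma^2)
    height_c1: float
    height_sigma: float = 0.15
    max_height: float = 27.5  # m, canopy ceiling: the log-log curve is clipped here
    crown_radius_coef: float = 0.55  # crown radius = coef * D^exp (m, D in cm)
    crown_radius_exp: float = 0.6
    crown_depth_ratio: float = 0.45  # crown depth as a fraction of tree height
    min_dbh: float = 5.0  # census threshold, cm
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.species_mix:
            raise ValueError("species mixture must not be empty")
        if self.stem_density <= 0:
            raise ValueError("stem density must be positive")
        total = sum(s.abundance for s in self.species_mix)
        if total <= 0:
            raise ValueError("species abundances must sum to a positive value")
        for s in self.species_mix:
            s.abundance /= total
            if s.wood_density <= 0:
                raise ValueError(f"non-positive wood density for {s.species}")


@dataclass
class SensorConfig:
    """Lidar acquisition model.

    Defaults follow a UAS-mounted triple-echo scanner: ~300 returns/m^2,
    centimetre-level ranging noise, and a small rate of gross outliers.
    """

    pulse_density: float = 300.0  # pulses per m^2
    max_returns: int = 3
    noise_sd: float = 0.03  # m, vertical Gaussian ranging noise
    outlier_fraction: float = 0.001
    outlier_range: tuple[float, float] = (20.0, 80.0)  # m above/below the scene
    canopy_transmittance: float = 0.35  # per-crown probability a pulse continues

    def __post_init__(self) -> None:
        if self.pulse_density <= 0:
            raise ValueError("pulse density must be positive")
        if not 1 <= self.max_returns <= 3:
            raise ValueError("max_returns must be in 1..3")
        if not 0 <= self.outlier_fraction <= 1:
            raise ValueError("outlier fraction must be in [0, 1]")
        if not 0 <= self.canopy_transmittance <= 1:
            raise ValueError("canopy transmittance must be in [0, 1]")


# Species summaries (species, genus, % abundance, mean DBH cm, DBH range cm,
# mean height m) for the two default wet-Miombo site configurations.
_MWEKERA_SPECIES = [
    ("Julbernardia paniculata", "Julbernardia", 18.5, 31.03, (13.5, 59.9), 17.79),
    ("Isoberlinia angolensis", "Isoberlinia", 16.6, 23.92, (9.9, 44.7), 14.55),
    ("Marquesia macroura", "Marquesia", 15.7, 29.21, (5.3, 70.0), 15.10),
    ("Brachystegia longifolia", "Brachystegia", 9.3, 20.65, (11.8, 64.0), 11.27),
    ("Brachystegia spiciformis", "Brachystegia", 7.4, 18.55, (5.0, 64.2), 9.97),
    ("Parinari curatellifolia", "Parinari", 2.6, 23.48, (6.0, 53.5), 13.67),
    ("Ochna pulchra", "Ochna", 2.5, 7.62, (5.2, 10.9), 5.70),
    ("Baphia bequaertii", "Baphia", 2.3, 11.63, (5.8, 23.7), 6.95),
    ("Pericopsis angolensis", "Pericopsis", 2.3, 24.42, (10.3, 70.0), 14.01),
    ("Diplorhynchus condylocarpon", "Diplorhynchus", 2.0, 8.94, (5.0, 18.0), 7.64),
]

_MIENGWE_SPECIES = [
    ("Brachystegia longifolia", "Brachystegia", 22.1, 22.6, (7.7, 81.0), 13.68),
    ("Diplorhynchus condylocarpon", "Diplorhynchus", 11.4, 9.4, (5.0, 30.9), 8.26),
    ("Baphia bequaertii", "Baphia", 9.3, 12.8, (5.2, 25.1), 7.78),
    ("Isoberlinia angolensis", "Isoberlinia", 8.1, 17.9, (6.4, 59.2), 12.50),
    ("Pseudolachnostylis maprouneifolia", "Pseudolachnostylis", 6.0, 13.6, (5.2, 24.7), 8.33),
    ("Combretum zeyheri", "Combretum", 5.3, 9.2, (5.1, 15.3), 9.05),
    ("Julbernardia paniculata", "Julbernardia", 4.9, 41.7, (20.0, 98.3), 16.88),
    ("Pericopsis angolensis", "Pericopsis", 3.9, 20.8, (6.4, 47.0), 11.33),
    ("Ochna schweinfurthiana", "Ochna", 3.7, 8.8, (5.8, 13.5), 7.61),
    ("Combretum collinum", "Combretum", 3.7, 11.4, (5.5, 21.7), 9.73),
]


def _site_config(site: str, rows, stem_density: float, seed: int) -> StandConfig:
    mix = []
    ln_d, ln_h = [], []
    for species, genus, abundance, dbh_mean, dbh_range, h_mean in rows:
        sigma = max(math.log(dbh_range[1] / dbh_range[0]) / 4.0, 0.15)
        mix.append(
            SpeciesParams(
                species, genus, abundance, WOOD_DENSITY_G_CM3[genus], dbh_mean, sigma,
                dbh_max=1.2 * dbh_range[1],
            )
        )
        ln_d.append(math.log(dbh_mean))
        ln_h.append(math.log(h_mean))
    c1, c0 = np.polyfit(ln_d, ln_h, 1)
    return StandConfig(
        site=site,
        stem_density=stem_density,
        species_mix=mix,
        height_c0=float(c0),
        height_c1=float(c1),
        seed=seed,
    )


def mwekera_like_config(seed: int = 0, stem_density: float = 420.0) -> StandConfig:
    """Default stand for the first (taller, Julbernardia-led) site."""
    return _site_config("Mwekera", _MWEKERA_SPECIES, stem_density, seed)


def miengwe_like_config(seed: int = 0, stem_density: float = 480.0) -> StandConfig:
    """Default stand for the second (Brachystegia-led) site."""
    return _site_config("Miengwe", _MIENGWE_SPECIES, stem_density, seed)


def wood_density_table() -> pd.DataFrame:
    """The generator's genus-level wood density lookup as a tidy table."""
    rows = []
    for site_rows in (_MWEKERA_SPECIES, _MIENGWE_SPECIES):
        for species, genus, *_ in site_rows:
            rows.append(
                {
                    "species": species,
                    "genus": genus,
                    "density_g_cm3": WOOD_DENSITY_G_CM3[genus],
                }
            )
    return pd.DataFrame(rows).drop_duplicates("species").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Stand generation


def generate_stand(
    terrain: TerrainModel,
    config: StandConfig,
    bounds: tuple[float, float, float, float] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a tree list over `bounds` (default: the full terrain extent).

    Tree count is Poisson with mean ``stem_density x area``; positions are
    uniform; species follow the mixture; DBH is lognormal per species
    truncated at the census threshold (5 cm); height follows the site's
    log-log height-diameter curve with lognormal scatter, floored just
    above breast height. Crown radius and depth are derived
    allometrically for the lidar simulator.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    if bounds is None:
        x0, y0 = terrain.origin
        bounds = (x0, y0, x0 + terrain.extent_x, y0 + terrain.extent_y)
    xmin, ymin, xmax, ymax = bounds
    area_ha = (xmax - xmin) * (ymax - ymin) / 1e4
    n = rng.poisson(config.stem_density * area_ha)

    mix = config.species_mix
    probs = np.array([s.abundance for s in mix])
    comp = rng.choice(len(mix), size=n, p=probs)
    x = rng.uniform(xmin, xmax, n)
    y = rng.uniform(ymin, ymax, n)

    dbh = np.empty(n)
    for i, sp in enumerate(mix):
        m = comp == i
        k = int(m.sum())
        if k == 0:
            continue
        mu = math.log(sp.dbh_mean) - sp.dbh_sigma_ln**2 / 2.0
        d = rng.lognormal(mu, sp.dbh_sigma_ln, k)
        for _ in range(100):  # resample outside the truncation window
            out_of_range = (d < config.min_dbh) | (d > sp.dbh_max)
            if not out_of_range.any():
                break
            d[out_of_range] = rng.lognormal(mu, sp.dbh_sigma_ln, int(out_of_range.sum()))
        dbh[m] = np.clip(d, config.min_dbh, sp.dbh_max)

    height = np.exp(
        config.height_c0
        + config.height_c1 * np.log(dbh)
        + rng.normal(0.0, config.height_sigma, n)
    )
    height = np.clip(height, 1.3 + 1e-6, config.max_height)

    crown_radius = config.crown_radius_coef * dbh**config.crown_radius_exp
    crown_depth = config.crown_depth_ratio * height

    return pd.DataFrame(
        {
            "species": [mix[i].species for i in comp],
            "genus": [mix[i].genus for i in comp],
            "dbh_cm": dbh,
            "height_m": height,
            "wood_density": [mix[i].wood_density for i in comp],
            "x": x,
            "y": y,
            "crown_radius": crown_radius,
            "crown_depth": crown_depth,
        }
    )


# ---------------------------------------------------------------------------
# Lidar simulation


def simulate_point_cloud(
    terrain: TerrainModel,
    trees: pd.DataFrame,
    sensor: SensorConfig,
    seed: int = 0,
    bounds: tuple[float, float, float, float] | None = None,
) -> tuple[PointCloud, pd.DataFrame]:
    """Simulate a triple-echo cloud over `bounds`.

    Pulses sit on a jittered square grid at the configured density. A
    pulse intersecting crowns returns first from the highest crown
    envelope; it reaches the ground with probability
    ``transmittance^n_crowns``, in which case the last echo is a ground
    return and (if three echoes are allowed and a second crown exists) an
    intermediate echo is placed on the second-highest crown envelope.
    Open-ground pulses give single ground returns. All elevations get
    Gaussian noise; a configured fraction of gross outliers is appended.

    Returns the cloud and an aligned truth table with columns
    ``true_class`` (ground|canopy|outlier) and ``true_terrain_z``.
    """
    rng = np.random.default_rng(seed)
    if bounds is None:
        x0, y0 = terrain.origin
        bounds = (x0, y0, x0 + terrain.extent_x, y0 + terrain.extent_y)
    xmin, ymin, xmax, ymax = bounds

    spacing = 1.0 / math.sqrt(sensor.pulse_density)
    nx = max(int(round((xmax - xmin) / spacing)), 1)
    ny = max(int(round((ymax - ymin) / spacing)), 1)
    gx = xmin + (np.arange(nx)[None, :] + rng.uniform(0, 1, (ny, nx))) * (xmax - xmin) / nx
    gy = ymin + (np.arange(ny)[:, None] + rng.uniform(0, 1, (ny, nx))) * (ymax - ymin) / ny
    px = gx.ravel()
    py = gy.ravel()
    n_pulses = px.size

    top1 = np.full(n_pulses, -np.inf)
    top2 = np.full(n_pulses, -np.inf)
    n_crowns = np.zeros(n_pulses, dtype=np.int64)

    if len(trees):
        tx = trees["x"].to_numpy()
        ty = trees["y"].to_numpy()
        tr = trees["crown_radius"].to_numpy()
        th = trees["height_m"].to_numpy()
        td = trees["crown_depth"].to_numpy()
        tz = np.asarray(terrain.elevation(tx, ty), dtype=float)
        crown_top = tz + th
        crown_center = crown_top - td / 2.0
        rmax = float(tr.max())
        tree_kd = cKDTree(np.column_stack([tx, ty]))
        pulse_kd = cKDTree(np.column_stack([px, py]))
        pairs = pulse_kd.query_ball_tree(tree_kd, r=rmax)
        # flatten pulse->trees adjacency
        counts = np.fromiter((len(p) for p in pairs), dtype=np.int64, count=n_pulses)
        if counts.sum():
            pulse_idx = np.repeat(np.arange(n_pulses), counts)
            tree_idx = np.concatenate([np.asarray(p, dtype=np.int64) for p in pairs if p])
            d = np.hypot(px[pulse_idx] - tx[tree_idx], py[pulse_idx] - ty[tree_idx])
            hit = d < tr[tree_idx]
            pulse_idx, tree_idx, d = pulse_idx[hit], tree_idx[hit], d[hit]
            # upper ellipsoid surface under a vertical ray
            frac = np.sqrt(1.0 - (d / tr[tree_idx]) ** 2)
            zs = crown_center[tree_idx] + (td[tree_idx] / 2.0) * frac
            # per-pulse top-two surfaces
            order = np.lexsort((-zs, pulse_idx))
            ps, zs_sorted = pulse_idx[order], zs[order]
            first_in_seg = np.ones(ps.size, dtype=bool)
            first_in_seg[1:] = ps[1:] != ps[:-1]
            top1[ps[first_in_seg]] = zs_sorted[first_in_seg]
            second = np.zeros(ps.size, dtype=bool)
            second[1:] = (~first_in_seg[1:]) & first_in_seg[:-1]
            top2[ps[second]] = zs_sorted[second]
            np.add.at(n_crowns, pulse_idx, 0)
            n_crowns = np.bincount(pulse_idx, minlength=n_pulses)

    ground_z = np.asarray(terrain.elevation(px, py), dtype=float)
    has_canopy = n_crowns > 0
    reaches_ground = np.ones(n_pulses, dtype=bool)
    if has_canopy.any():
        reaches_ground[has_canopy] = (
            rng.uniform(0, 1, int(has_canopy.sum()))
            < sensor.canopy_transmittance ** n_crowns[has_canopy]
        )
    if sensor.max_returns < 2:
        reaches_ground &= ~has_canopy

    xs, ys, zs_out, rn, nr, true_cls, true_tz = [], [], [], [], [], [], []

    def emit(mask, z, number, total, cls):
        xs.append(px[mask])
        ys.append(py[mask])
        zs_out.append(z[mask] if isinstance(z, np.ndarray) else z)
        rn.append(np.full(int(mask.sum()), number, dtype=np.int64))
        nr.append(total[mask] if isinstance(total, np.ndarray) else
                  np.full(int(mask.sum()), total, dtype=np.int64))
        true_cls.append(np.full(int(mask.sum()), cls))
        true_tz.append(ground_z[mask])

    open_ground = ~has_canopy
    emit(open_ground, ground_z, 1, 1, "ground")

    canopy = has_canopy
    triple = canopy & reaches_ground & (top2 > -np.inf) & (sensor.max_returns >= 3)
    double = canopy & reaches_ground & ~triple & (sensor.max_returns >= 2)
    single = canopy & ~(triple | double)

    emit(single, top1, 1, 1, "canopy")
    emit(double, top1, 1, 2, "canopy")
    emit(double, ground_z, 2, 2, "ground")
    emit(triple, top1, 1, 3, "canopy")
    emit(triple, top2, 2, 3, "canopy")
    emit(triple, ground_z, 3, 3, "ground")

    x = np.concatenate(xs)
    y = np.concatenate(ys)
    z = np.concatenate(zs_out) + rng.normal(0.0, sensor.noise_sd, sum(a.size for a in xs))
    rn_a = np.concatenate(rn)
    nr_a = np.concatenate(nr)
    cls_a = np.concatenate(true_cls)
    tz_a = np.concatenate(true_tz)

    n_out = int(round(sensor.outlier_fraction * x.size))
    if n_out:
        ox = rng.uniform(xmin, xmax, n_out)
        oy = rng.uniform(ymin, ymax, n_out)
        lo, hi = sensor.outlier_range
        mag = rng.uniform(lo, hi, n_out)
        sign = rng.choice([-1.0, 1.0], n_out)
        base = np.asarray(terrain.elevation(ox, oy), dtype=float)
        oz = base + sign * mag
        x = np.concatenate([x, ox])
        y = np.concatenate([y, oy])
        z = np.concatenate([z, oz])
        rn_a = np.concatenate([rn_a, np.ones(n_out, dtype=np.int64)])
        nr_a = np.concatenate([nr_a, np.ones(n_out, dtype=np.int64)])
        cls_a = np.concatenate([cls_a, np.full(n_out, "outlier")])
        tz_a = np.concatenate([tz_a, base])

    cloud = PointCloud(x, y, z, rn_a, nr_a,
                       np.full(x.size, CLASS_UNCLASSIFIED, dtype=np.int64))
    truth = pd.DataFrame({"true_class": cls_a, "true_terrain_z": tz_a})
    return cloud, truth


# ---------------------------------------------------------------------------
# Site-level convenience


@dataclass
class SiteData:
    """One simulated site: plots, tree lists, and per-plot raw clouds."""

    site: str
    terrain: TerrainModel
    plots: pd.DataFrame  # plot_id, site, x, y, radius
    trees: pd.DataFrame  # all trees in the simulated tiles; plot_id set for in-plot trees
    clouds: dict[str, PointCloud]
    truths: dict[str, pd.DataFrame]

    @property
    def field_trees(self) -> pd.DataFrame:
        """Trees inside plot footprints (the simulated field census)."""
        return self.trees[self.trees["plot_id"] != ""].reset_index(drop=True)


def simulate_site(
    stand_config: StandConfig,
    sensor_config: SensorConfig | None = None,
    n_plots: int = 16,
    plot_radius: float = 20.0,
    plot_spacing: float = 200.0,
    tile_buffer: float = 3.0,
    relief_amplitude: float = 5.0,
    base_elevation: float = 1225.0,
    seed: int | None = None,
) -> SiteData:
    """Simulate a full site: a plot grid with one lidar tile per plot.

    Plots are laid on a square grid at ``plot_spacing``; around each plot
    a square tile of half-width ``plot_radius + tile_buffer`` is
    populated with trees and scanned, which keeps simulation cost
    proportional to the sampled area while letting crowns of off-plot
    trees overhang plot edges as they would in reality.
    """
    if sensor_config is None:
        sensor_config = SensorConfig()
    if seed is None:
        seed = stand_config.seed
    rng = np.random.default_rng(seed)

    n_side = int(math.ceil(math.sqrt(n_plots)))
    extent = n_side * plot_spacing
    terrain = generate_terrain(
        (extent, extent),
        relief_amplitude=relief_amplitude,
        seed=int(rng.integers(2**31 - 1)),
        base_elevation=base_elevation,
    )

    plot_rows = []
    all_trees = []
    clouds: dict[str, PointCloud] = {}
    truths: dict[str, pd.DataFrame] = {}
    half = plot_radius + tile_buffer
    for i in range(n_plots):
        r, c = divmod(i, n_side)
        cx = (c + 0.5) * plot_spacing
        cy = (r + 0.5) * plot_spacing
        plot_id = f"{stand_config.site}-{i + 1:02d}"
        plot_rows.append(
            {"plot_id": plot_id, "site": stand_config.site, "x": cx, "y": cy,
             "radius": plot_radius}
        )
        tile = (cx - half, cy - half, cx + half, cy + half)
        trees = generate_stand(terrain, stand_config, bounds=tile,
                               seed=int(rng.integers(2**31 - 1)))
        d = np.hypot(trees["x"] - cx, trees["y"] - cy)
        trees = trees.assign(plot_id=np.where(d <= plot_radius, plot_id, ""))
        all_trees.append(trees)
        cloud, truth = simulate_point_cloud(
            terrain, trees, sensor_config, seed=int(rng.integers(2**31 - 1)), bounds=tile
        )
        clouds[plot_id] = cloud
        truths[plot_id] = truth

    return SiteData(
        site=stand_config.site,
        terrain=terrain,
        plots=pd.DataFrame(plot_rows),
        trees=pd.concat(all_trees, ignore_index=True),
        clouds=clouds,
        truths=truths,
    )
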