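"""Point-cloud containers and pre-processing.

The processing chain mirrors a standard area-based lidar inventory
workflow: statistical outlier removal, ground classification by
progressive TIN densification, bare-earth (DTM) interpolation by inverse
distance weighting, and height normalization of every return against the
DTM.

Point clouds are stored as flat numpy arrays (one row per return) with
ASPRS-style class codes: 1 = unclassified, 2 = ground, 7 = noise.
Interchange format is a plain CSV with columns
``x,y,z,return_number,number_of_returns[,classification]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree

CLASS_UNCLASSIFIED = 1
CLASS_GROUND = 2
CLASS_NOISE = 7

_CSV_COLUMNS = ["x", "y", "z", "return_number", "number_of_returns"]


@dataclass
class PointCloud:
    """Georeferenced lidar returns.

    ``z`` holds elevations (m above datum) for raw clouds and heights
    above ground (m) after :func:`normalize_heights`; ``normalized``
    records which of the two it currently is.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    return_number: np.ndarray
    number_of_returns: np.ndarray
    classification: np.ndarray = None  # type: ignore[assignment]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.return_number = np.asarray(self.return_number, dtype=np.int64)
        self.number_of_returns = np.asarray(self.number_of_returns, dtype=np.int64)
        if self.classification is None:
            self.classification = np.full(self.x.size, CLASS_UNCLASSIFIED, dtype=np.int64)
        else:
            self.classification = np.asarray(self.classification, dtype=np.int64)
        n = self.x.size
        for name in ("y", "z", "return_number", "number_of_returns", "classification"):
            if getattr(self, name).size != n:
                raise ValueError(f"field {name!r} length mismatch with x")
        if n and not (np.isfinite(self.x).all() and np.isfinite(self.y).all() and np.isfinite(self.z).all()):
            raise ValueError("point coordinates must be finite")
        bad = (self.return_number < 1) | (self.return_number > self.number_of_returns) | (
            self.number_of_returns > 3
        )
        if bad.any():
            raise ValueError("require 1 <= return_number <= number_of_returns <= 3")

    def __len__(self) -> int:
        return int(self.x.size)

    @property
    def is_first_return(self) -> np.ndarray:
        return self.return_number == 1

    def select(self, mask: np.ndarray) -> "PointCloud":
        return PointCloud(
            self.x[mask],
            self.y[mask],
            self.z[mask],
            self.return_number[mask],
            self.number_of_returns[mask],
            self.classification[mask],
            normalized=self.normalized,
        )

    def without_noise(self) -> "PointCloud":
        return self.select(self.classification != CLASS_NOISE)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.x,
                "y": self.y,
                "z": self.z,
                "return_number": self.return_number,
                "number_of_returns": self.number_of_returns,
                "classification": self.classification,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, normalized: bool = False) -> "PointCloud":
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"point cloud table missing columns {missing}")
        cls_col = df["classification"].to_numpy() if "classification" in df.columns else None
        return cls(
            df["x"].to_numpy(),
            df["y"].to_numpy(),
            df["z"].to_numpy(),
            df["return_number"].to_numpy(),
            df["number_of_returns"].to_numpy(),
            cls_col,
            normalized=normalized,
        )

    @classmethod
    def from_csv(cls, path, normalized: bool = False) -> "PointCloud":
        return cls.from_dataframe(pd.read_csv(path), normalized=normalized)


@dataclass
class DTMRaster:
    """Bare-earth elevation raster, lower-left origin, row 0 at the south edge.

    Cell (i, j) covers the half-open square
    ``[x0 + j*c, x0 + (j+1)*c) x [y0 + i*c, y0 + (i+1)*c)`` and its value is
    the interpolated elevation at the cell centre.
    """

    x0: float
    y0: float
    cell_size: float
    values: np.ndarray  # shape (n_rows, n_cols)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")
        if self.values.ndim != 2:
            raise ValueError("DTM values must be 2-D")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys

    def sample_bilinear(self, x, y) -> np.ndarray:
        """Bilinear interpolation between cell centres; edge cells clamp.

        Raises for query points outside the raster footprint, reporting the
        offending cell index.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        c = self.cell_size
        col = np.floor((x - self.x0) / c).astype(int)
        row = np.floor((y - self.y0) / c).astype(int)
        outside = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        if outside.any():
            i = int(np.argmax(outside))
            raise ValueError(
                f"point ({x[i]:.2f}, {y[i]:.2f}) outside DTM coverage "
                f"(cell index row={row[i]}, col={col[i]})"
            )
        # fractional position relative to cell-centre lattice
        gx = np.clip((x - self.x0) / c - 0.5, 0.0, self.n_cols - 1.0)
        gy = np.clip((y - self.y0) / c - 0.5, 0.0, self.n_rows - 1.0)
        j0 = np.floor(gx).astype(int)
        i0 = np.floor(gy).astype(int)
        j1 = np.minimum(j0 + 1, self.n_cols - 1)
        i1 = np.minimum(i0 + 1, self.n_rows - 1)
        tx = gx - j0
        ty = gy - i0
        v = self.values
        return (
            v[i0, j0] * (1 - tx) * (1 - ty)
            + v[i0, j1] * tx * (1 - ty)
            + v[i1, j0] * (1 - tx) * ty
            + v[i1, j1] * tx * ty
        )

    def to_ascii(self, path) -> None:
        """Write as ESRI ASCII grid (north-up row order on disk)."""
        with open(path, "w") as fh:
            fh.write(f"ncols {self.n_cols}\n")
            fh.write(f"nrows {self.n_rows}\n")
            fh.write(f"xllcorner {self.x0}\n")
            fh.write(f"yllcorner {self.y0}\n")
            fh.write(f"cellsize {self.cell_size}\n")
            fh.write(f"NODATA_value {self.nodata}\n")
            vals = np.where(np.isfinite(self.values), self.values, self.nodata)
            for r in vals[::-1]:  # ESRI stores top row first
                fh.write(" ".join(f"{v:.4f}" for v in r) + "\n")

    @classmethod
    def from_ascii(cls, path) -> "DTMRaster":
        header: dict[str, float] = {}
        rows: list[list[float]] = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if parts[0].lower() in {
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
                }:
                    header[parts[0].lower()] = float(parts[1])
                else:
                    rows.append([float(v) for v in parts])
        values = np.asarray(rows)[::-1]  # back to south-up
        nodata = header.get("nodata_value", -9999.0)
        values = np.where(values == nodata, np.nan, values)
        return cls(
            header["xllcorner"], header["yllcorner"], header["cellsize"], values, nodata
        )


def denoise(cloud: PointCloud, k_neighbors: int = 10, std_multiplier: float = 3.0) -> PointCloud:
    """Flag gross outliers by the mean-distance-to-neighbours rule.

    Each point's mean 3-D distance to its ``k_neighbors`` nearest
    neighbours is compared against the global mean plus
    ``std_multiplier`` standard deviations of those distances; points
    beyond the threshold are relabelled as noise (class 7) but retained,
    so the operation is a pure relabelling. Points already marked noise
    are ignored and keep their label.
    """
    if len(cloud) == 0:
        raise ValueError("cannot denoise an empty cloud")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if std_multiplier <= 0:
        raise ValueError("std_multiplier must be positive")
    live = cloud.classification != CLASS_NOISE
    n_live = int(live.sum())
    if k_neighbors >= n_live:
        raise ValueError(f"k_neighbors={k_neighbors} must be < number of points ({n_live})")
    pts = np.column_stack([cloud.x[live], cloud.y[live], cloud.z[live]])
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=k_neighbors + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    cutoff = mean_d.mean() + std_multiplier * mean_d.std()
    flagged = mean_d > cutoff
    new_class = cloud.classification.copy()
    idx = np.flatnonzero(live)[flagged]
    new_class[idx] = CLASS_NOISE
    return replace(cloud, classification=new_class)


def _lowest_per_cell(x: np.ndarray, y: np.ndarray, z: np.ndarray, cell: float) -> np.ndarray:
    """Indices of the lowest point in each occupied `cell` x `cell` square."""
    ci = np.floor(x / cell).astype(np.int64)
    cj = np.floor(y / cell).astype(np.int64)
    key = (ci - ci.min()) * (cj.max() - cj.min() + 1) + (cj - cj.min())
    order = np.lexsort((z, key))
    key_sorted = key[order]
    first = np.ones(key_sorted.size, dtype=bool)
    first[1:] = key_sorted[1:] != key_sorted[:-1]
    return order[first]


def classify_ground(
    cloud: PointCloud,
    grid_cell: float = 20.0,
    angle_threshold_deg: float = 8.0,
    distance_threshold_m: float = 1.4,
    close_distance_m: float = 0.2,
    max_iterations: int = 50,
) -> PointCloud:
    """Progressive TIN densification ground filter.

    Seeds a sparse TIN with the lowest return of each coarse grid cell
    (assumed bare earth), then repeatedly adds candidate points whose
    vertical distance to the enclosing TIN facet and whose maximum
    point-to-vertex angle against that facet are both below the
    thresholds, rebuilding the TIN until a fixed point. Added points are
    labelled ground (class 2). Noise-classed points are excluded from
    consideration.

    At survey-grade pulse densities TIN facets shrink to the point
    spacing, which makes the vertex-angle test reject points lying only
    ranging-noise distances off the facet; points within
    ``close_distance_m`` of the facet are therefore accepted on the
    distance criterion alone. The angle rule still governs at larger
    distances, which is where vegetation is rejected.
    """
    live_mask = cloud.classification != CLASS_NOISE
    x, y, z = cloud.x[live_mask], cloud.y[live_mask], cloud.z[live_mask]
    if x.size < 3:
        raise ValueError("ground classification needs at least 3 non-noise points")

    seed_idx = _lowest_per_cell(x, y, z, grid_cell)
    is_ground = np.zeros(x.size, dtype=bool)
    is_ground[seed_idx] = True
    if seed_idx.size < 3:
        # degenerate extent: fall back to the three lowest points
        is_ground[np.argsort(z)[:3]] = True

    # Virtual corner vertices make the seed TIN span the whole bounding box;
    # they take the elevation of the nearest seed and are never labelled.
    pad = 1e-6 * max(np.ptp(x), np.ptp(y), 1.0)
    corners_xy = np.array(
        [
            [x.min() - pad, y.min() - pad],
            [x.min() - pad, y.max() + pad],
            [x.max() + pad, y.min() - pad],
            [x.max() + pad, y.max() + pad],
        ]
    )
    seed_tree = cKDTree(np.column_stack([x[is_ground], y[is_ground]]))
    _, nearest = seed_tree.query(corners_xy)
    corners_z = z[np.flatnonzero(is_ground)[nearest]]

    tan_dist = distance_threshold_m
    angle_rad = np.deg2rad(angle_threshold_deg)

    for _ in range(max_iterations):
        gidx = np.flatnonzero(is_ground)
        vx = np.concatenate([x[gidx], corners_xy[:, 0]])
        vy = np.concatenate([y[gidx], corners_xy[:, 1]])
        vz = np.concatenate([z[gidx], corners_z])
        gxy = np.column_stack([vx, vy])
        # Qhull needs non-degenerate input; guard for collinear seeds
        try:
            tri = Delaunay(gxy)
        except Exception:  # collinear seeds: accept everything near the lowest plane
            break
        cand = np.flatnonzero(~is_ground)
        if cand.size == 0:
            break
        cxy = np.column_stack([x[cand], y[cand]])
        simplex = tri.find_simplex(cxy)
        inside = simplex >= 0
        if not inside.any():
            break
        cand = cand[inside]
        v = tri.simplices[simplex[inside]]  # (m, 3) indices into vertex arrays
        p0 = np.column_stack([vx[v[:, 0]], vy[v[:, 0]], vz[v[:, 0]]])
        p1 = np.column_stack([vx[v[:, 1]], vy[v[:, 1]], vz[v[:, 1]]])
        p2 = np.column_stack([vx[v[:, 2]], vy[v[:, 2]], vz[v[:, 2]]])
        nrm = np.cross(p1 - p0, p2 - p0)
        nz = nrm[:, 2]
        nz = np.where(np.abs(nz) < 1e-12, 1e-12, nz)
        pc = np.column_stack([x[cand], y[cand], z[cand]])
        # vertical distance point -> facet plane
        dz = pc[:, 2] - (
            p0[:, 2] - (nrm[:, 0] * (pc[:, 0] - p0[:, 0]) + nrm[:, 1] * (pc[:, 1] - p0[:, 1])) / nz
        )
        dist = np.abs(dz)
        ok = dist < tan_dist
        if ok.any():
            # max angle between facet and point-vertex lines
            max_sin = np.zeros(cand.size)
            for pv in (p0, p1, p2):
                seg = np.linalg.norm(pc - pv, axis=1)
                seg = np.where(seg < 1e-12, 1e-12, seg)
                max_sin = np.maximum(max_sin, dist / seg)
            angle_ok = np.arcsin(np.clip(max_sin, 0.0, 1.0)) < angle_rad
            ok &= angle_ok | (dist < close_distance_m)
        if not ok.any():
            break
        is_ground[cand[ok]] = True
        if ok.sum() < max(cand.size // 1000, 10) and is_ground.sum() > seed_idx.size * 4:
            break  # diminishing additions: densification has converged

    new_class = cloud.classification.copy()
    live_idx = np.flatnonzero(live_mask)
    new_class[live_idx[is_ground]] = CLASS_GROUND
    keep_unclassified = live_idx[~is_ground]
    new_class[keep_unclassified] = np.where(
        new_class[keep_unclassified] == CLASS_GROUND, CLASS_UNCLASSIFIED, new_class[keep_unclassified]
    )
    return replace(cloud, classification=new_class)


def build_dtm(
    cloud: PointCloud,
    cell_size: float = 1.0,
    idw_power: float = 2.0,
    n_neighbors: int = 12,
    bounds: tuple[float, float, float, float] | None = None,
) -> DTMRaster:
    """Interpolate ground returns to a bare-earth raster by IDW.

    Each cell-centre elevation is the inverse-distance-power weighted
    mean of the ``n_neighbors`` nearest ground points; a ground point
    coincident with the cell centre short-circuits to that point's
    elevation. ``bounds`` (xmin, ymin, xmax, ymax) defaults to the ground
    points' bounding box.
    """
    gmask = cloud.classification == CLASS_GROUND
    gx, gy, gz = cloud.x[gmask], cloud.y[gmask], cloud.z[gmask]
    if gx.size == 0:
        raise ValueError("no ground points to interpolate")
    if cell_size <= 0:
        raise ValueError("cell size must be positive")
    if bounds is None:
        bounds = (gx.min(), gy.min(), gx.max(), gy.max())
    xmin, ymin, xmax, ymax = bounds
    n_cols = max(int(np.ceil((xmax - xmin) / cell_size)), 1)
    n_rows = max(int(np.ceil((ymax - ymin) / cell_size)), 1)
    xs = xmin + (np.arange(n_cols) + 0.5) * cell_size
    ys = ymin + (np.arange(n_rows) + 0.5) * cell_size
    XX, YY = np.meshgrid(xs, ys)
    centers = np.column_stack([XX.ravel(), YY.ravel()])

    k = min(n_neighbors, gx.size)
    tree = cKDTree(np.column_stack([gx, gy]))
    dist, idx = tree.query(centers, k=k)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    exact = dist[:, 0] < 1e-12
    with np.errstate(divide="ignore"):
        w = dist ** (-idw_power)
    w[~np.isfinite(w)] = 0.0
    num = (w * gz[idx]).sum(axis=1)
    den = w.sum(axis=1)
    den = np.where(den == 0, 1.0, den)
    vals = num / den
    vals[exact] = gz[idx[exact, 0]]
    return DTMRaster(xmin, ymin, cell_size, vals.reshape(n_rows, n_cols))


def normalize_heights(cloud: PointCloud, dtm: DTMRaster) -> PointCloud:
    """Convert elevations to heights above ground via the DTM.

    Subtracts the bilinearly interpolated DTM elevation under each
    return. Slightly negative heights (ground returns below the
    interpolated surface) are retained, not clamped; the canopy height
    threshold applied during metric extraction makes clamping
    unnecessary.
    """
    heights = cloud.z - dtm.sample_bilinear(cloud.x, cloud.y)
    out = replace(cloud, z=heights)
    out.normalized = True
    return out


def preprocess(
    cloud: PointCloud,
    denoise_k: int = 10,
    denoise_mult: float = 3.0,
    ptin_cell: float = 20.0,
    ptin_angle_deg: float = 8.0,
    ptin_dist_m: float = 1.4,
    ptin_close_m: float = 0.2,
    dtm_cell: float = 1.0,
    idw_power: float = 2.0,
    idw_n: int = 12,
) -> tuple[PointCloud, DTMRaster]:
    """Full raw-cloud pipeline: denoise -> ground filter -> DTM -> normalize.

    Returns the normalized cloud (noise returns dropped) and the DTM.
    """
    cloud = denoise(cloud, denoise_k, denoise_mult)
    cloud = classify_ground(cloud, ptin_cell, ptin_angle_deg, ptin_dist_m, ptin_close_m)
    clean = cloud.without_noise()
    pad = dtm_cell  # cover the full cloud footprint, not just the ground bbox
    bounds = (
        clean.x.min() - pad,
        clean.y.min() - pad,
        clean.x.max() + pad,
        clean.y.max() + pad,
    )
    dtm = build_dtm(clean, dtm_cell, idw_power, idw_n, bounds=bounds)
    return normalize_heights(clean, dtm), dtm
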