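"""Plot clipping and canopy height / density / cover metrics.

Metrics are computed from normalized clouds over a plot footprint with a
height threshold (default 2 m) separating canopy from ground-level
returns. Two return-set conventions are used, following common
area-based practice: height percentiles, mean height, and canopy cover
are computed from *first* returns (a proxy for the outer canopy
surface), while dispersion and shape statistics (variance, CV, skewness,
kurtosis, MAD-median, quadratic mean, relief ratio, height-range decile
densities) use *all* above-threshold returns.

Gap fraction is the complement of canopy cover and leaf area index is
obtained by Beer-Lambert inversion, LAI = -ln(GF)/k with extinction
coefficient k (default 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pointcloud import PointCloud

PERCENTILE_LEVELS = (1, 5, 10, 20, 25, 30, 40, 50, 60, 70, 75, 80, 90, 95, 99)

METRIC_NAMES = (
    [f"H{p}" for p in PERCENTILE_LEVELS]
    + [f"D{k}" for k in range(1, 10)]
    + [
        "Hvar", "Hmax", "Hcv", "Hmdm", "Hmsq", "Hskew", "Hkurtosis",
        "Hstd", "Hmean", "CRR", "CC", "GF", "LAI",
        "n_points", "n_first_returns",
    ]
)


@dataclass(frozen=True)
class PlotDefinition:
    """A circular field plot footprint."""

    plot_id: str
    site: str
    x: float
    y: float
    radius: float = 20.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("plot radius must be positive")


def clip_to_plot(cloud: PointCloud, plot: PlotDefinition) -> PointCloud:
    """Retain returns within the plot circle (boundary inclusive)."""
    d2 = (cloud.x - plot.x) ** 2 + (cloud.y - plot.y) ** 2
    return cloud.select(d2 <= plot.radius**2)


def clip_to_cell(cloud: PointCloud, x0: float, y0: float, cell: float) -> PointCloud:
    """Retain returns within the half-open square cell [x0, x0+cell) x [y0, y0+cell)."""
    m = (cloud.x >= x0) & (cloud.x < x0 + cell) & (cloud.y >= y0) & (cloud.y < y0 + cell)
    return cloud.select(m)


def compute_plot_metrics(
    cloud: PointCloud,
    height_threshold: float = 2.0,
    extinction_k: float = 0.5,
    gap_fraction_floor: float = 1e-4,
) -> dict[str, float]:
    """Compute the full metric vector for one clipped, normalized cloud.

    Degenerate inputs are signalled with NaNs: a plot with no first
    returns yields all-NaN metrics; a plot whose returns all sit below
    the threshold yields CC=0, GF=1, LAI=0 with NaN height metrics. CRR
    is NaN when all canopy heights coincide (zero range).
    """
    out: dict[str, float] = {name: np.nan for name in METRIC_NAMES}
    out["n_points"] = float(len(cloud))
    first = cloud.z[cloud.is_first_return]
    out["n_first_returns"] = float(first.size)
    if first.size == 0:
        return out

    cc = float((first > height_threshold).sum()) / first.size
    gf = 1.0 - cc
    out["CC"] = cc
    out["GF"] = gf
    out["LAI"] = -np.log(max(gf, gap_fraction_floor)) / extinction_k if cc > 0 else 0.0

    first_above = first[first > height_threshold]
    all_above = cloud.z[cloud.z > height_threshold]
    if all_above.size == 0:
        out["CC"], out["GF"], out["LAI"] = 0.0, 1.0, 0.0
        return out

    if first_above.size:
        pct = np.percentile(first_above, PERCENTILE_LEVELS)  # linear interpolation
        for lev, v in zip(PERCENTILE_LEVELS, pct):
            out[f"H{lev}"] = float(v)
        out["Hmean"] = float(first_above.mean())

    hmin = float(all_above.min())
    hmax = float(all_above.max())
    mean = float(all_above.mean())
    out["Hmax"] = hmax
    std = float(all_above.std(ddof=1)) if all_above.size > 1 else 0.0
    out["Hstd"] = std
    out["Hvar"] = std**2
    out["Hcv"] = std / mean if mean != 0 else np.nan
    med = float(np.median(all_above))
    out["Hmdm"] = float(np.median(np.abs(all_above - med)))
    out["Hmsq"] = float(np.sqrt(np.mean(all_above**2)))
    if std > 0:
        zc = (all_above - mean) / float(all_above.std(ddof=0))
        out["Hskew"] = float(np.mean(zc**3))
        out["Hkurtosis"] = float(np.mean(zc**4))
    else:
        out["Hskew"] = np.nan
        out["Hkurtosis"] = np.nan
    rng = hmax - hmin
    out["CRR"] = (mean - hmin) / rng if rng > 0 else np.nan
    for k in range(1, 10):
        if rng > 0:
            cut = hmin + (k / 10.0) * rng
            out[f"D{k}"] = float((all_above > cut).sum()) / all_above.size
        else:
            out[f"D{k}"] = 0.0
    return out


def metrics_table(
    cloud_by_plot: dict[str, PointCloud],
    plots: pd.DataFrame | None = None,
    height_threshold: float = 2.0,
    clip: bool = True,
    extinction_k: float = 0.5,
) -> pd.DataFrame:
    """Metric vectors for many plots as a wide table (one row per plot).

    ``cloud_by_plot`` maps plot_id to a normalized cloud covering the
    plot; if ``clip`` is true and ``plots`` provides footprints, each
    cloud is clipped to its circle first.
    """
    rows = []
    for plot_id, cloud in cloud_by_plot.items():
        if clip and plots is not None:
            p = plots.loc[plots["plot_id"] == plot_id].iloc[0]
            cloud = clip_to_plot(
                cloud, PlotDefinition(plot_id, str(p.get("site", "")), p["x"], p["y"],
                                      p["radius"])
            )
        row = {"plot_id": plot_id}
        row.update(compute_plot_metrics(cloud, height_threshold,
                                        extinction_k=extinction_k))
        rows.append(row)
    return pd.DataFrame(rows).set_index("plot_id")


def grid_metrics_table(
    cloud: PointCloud,
    cell: float = 40.0,
    height_threshold: float = 2.0,
    origin: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Metric vectors on a square grid (half-open cells), one row per cell."""
    if origin is None:
        origin = (float(cloud.x.min()), float(cloud.y.min()))
    x0, y0 = origin
    n_cols = int(np.ceil((cloud.x.max() - x0) / cell)) or 1
    n_rows = int(np.ceil((cloud.y.max() - y0) / cell)) or 1
    rows = []
    for i in range(n_rows):
        for j in range(n_cols):
            sub = clip_to_cell(cloud, x0 + j * cell, y0 + i * cell, cell)
            if len(sub) == 0:
                continue
            row = {"cell_id": f"r{i}c{j}", "row": i, "col": j}
            row.update(compute_plot_metrics(sub, height_threshold))
            rows.append(row)
    return pd.DataFrame(rows).set_index("cell_id")
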