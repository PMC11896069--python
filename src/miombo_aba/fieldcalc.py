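"""Per-tree allometry and plot-level forest structural attributes.

Converts a field tree census (DBH in cm, total height in m, wood density
in g/cm^3) into the four plot-level response variables of an area-based
inventory: aboveground biomass (AGB, Mg/ha), basal area (BA, m^2/ha),
mean diameter (DBH, cm) and stem volume (Vol, m^3/ha).

Tree AGB follows a mixed-variable power allometry on the compound
rho*D^2*H:

    ln(AGB) = ln(a) + b * ln(rho * D^2 * H)

i.e. AGB = a * (rho*D^2*H)^b in kg/tree. The coefficients are
site-calibration inputs; the shipped defaults (a=0.0673, b=0.976) are
generic moist-tropical values and should be replaced with locally fitted
ones for real inventories. Volume uses the form-factor model
Vol = BA * H * f with f = 0.74 by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

MIN_DBH_CM = 5.0


@dataclass
class AllometryParams:
    """Coefficients of the biomass and volume models."""

    a: float = 0.0673
    b: float = 0.976
    form_factor: float = 0.74
    #: lognormal error sd of the biomass model; used only when *simulating*
    #: field biomass, never in deterministic attribute computation
    error_sd: float = 0.0
    #: apply exp(sd^2/2) when converting simulated ln-scale draws back
    back_transform_correction: bool = False

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("allometry coefficient a must be positive")
        if not 0 < self.form_factor <= 1:
            raise ValueError("form factor must be in (0, 1]")


def lookup_wood_density(
    species: str,
    genus: str,
    table: pd.DataFrame,
    allow_mean_fallback: bool = False,
) -> float:
    """Wood density (g/cm^3) for a taxon from a lookup table.

    Exact species match wins; otherwise the arithmetic mean over
    same-genus entries; otherwise the all-table mean if the fallback is
    enabled, else an error naming the taxon.
    """
    if table is None or len(table) == 0:
        raise ValueError("wood density table is empty")
    hit = table.loc[table["species"] == species, "density_g_cm3"]
    if len(hit):
        return float(hit.iloc[0])
    gen = table.loc[table["genus"] == genus, "density_g_cm3"]
    if len(gen):
        return float(gen.mean())
    if allow_mean_fallback:
        return float(table["density_g_cm3"].mean())
    raise KeyError(f"no wood density for species {species!r} or genus {genus!r}")


def tree_agb(dbh_cm, height_m, wood_density, params: AllometryParams) -> np.ndarray | float:
    """Aboveground biomass of a tree, kg."""
    d = np.asarray(dbh_cm, dtype=float)
    h = np.asarray(height_m, dtype=float)
    rho = np.asarray(wood_density, dtype=float)
    if (d <= 0).any() or (h <= 0).any() or (rho <= 0).any():
        raise ValueError("DBH, height and wood density must be positive")
    out = params.a * (rho * d**2 * h) ** params.b
    return out if out.ndim else float(out)


def tree_basal_area(dbh_cm) -> np.ndarray | float:
    """Basal area of a stem, m^2 (DBH in cm; census threshold 5 cm)."""
    d = np.asarray(dbh_cm, dtype=float)
    if (d < MIN_DBH_CM).any():
        raise ValueError(f"DBH below the {MIN_DBH_CM} cm census threshold")
    out = math.pi * (d / 200.0) ** 2
    return out if out.ndim else float(out)


def tree_volume(dbh_cm, height_m, form_factor: float = 0.74) -> np.ndarray | float:
    """Stem volume, m^3, as basal area x height x form factor."""
    h = np.asarray(height_m, dtype=float)
    if (h <= 0).any():
        raise ValueError("height must be positive")
    if not 0 < form_factor <= 1:
        raise ValueError("form factor must be in (0, 1]")
    out = tree_basal_area(dbh_cm) * h * form_factor
    return out if np.ndim(out) else float(out)


def aggregate_plot(
    trees: pd.DataFrame,
    plot_id: str,
    plot_area_m2: float,
    params: AllometryParams | None = None,
    dbh_summary: str = "arithmetic",
) -> dict:
    """Plot-level attribute summary from its tree list.

    AGB/BA/Vol are summed over trees and scaled to per-hectare (factor
    1e4 / plot area); tree AGB in kg is converted to Mg. The plot DBH is
    the arithmetic mean of tree diameters by default (``dbh_summary =
    'quadratic'`` gives the quadratic mean). Empty plots return zeros
    with ``empty=True``.
    """
    if params is None:
        params = AllometryParams()
    if plot_area_m2 <= 0:
        raise ValueError("plot area must be positive")
    sub = trees.loc[trees["plot_id"] == plot_id] if "plot_id" in trees.columns else trees
    n = len(sub)
    if n == 0:
        return {"plot_id": plot_id, "AGB": 0.0, "BA": 0.0, "DBH": 0.0, "Vol": 0.0,
                "n_trees": 0, "empty": True}
    d = sub["dbh_cm"].to_numpy()
    h = sub["height_m"].to_numpy()
    rho = sub["wood_density"].to_numpy()
    scale = 1e4 / plot_area_m2
    agb_kg = np.asarray(tree_agb(d, h, rho, params))
    ba = np.asarray(tree_basal_area(d))
    vol = np.asarray(tree_volume(d, h, params.form_factor))
    if dbh_summary == "quadratic":
        dbh_plot = float(np.sqrt(np.mean(d**2)))
    elif dbh_summary == "arithmetic":
        dbh_plot = float(d.mean())
    else:
        raise ValueError(f"unknown dbh_summary {dbh_summary!r}")
    return {
        "plot_id": plot_id,
        "AGB": float(agb_kg.sum()) / 1e3 * scale,  # Mg/ha
        "BA": float(ba.sum()) * scale,  # m^2/ha
        "DBH": dbh_plot,  # cm
        "Vol": float(vol.sum()) * scale,  # m^3/ha
        "n_trees": n,
        "empty": False,
    }


def plot_attribute_table(
    trees: pd.DataFrame,
    plots: pd.DataFrame,
    params: AllometryParams | None = None,
    dbh_summary: str = "arithmetic",
) -> pd.DataFrame:
    """Attribute summaries for every plot in ``plots`` (circular footprints)."""
    rows = []
    for _, p in plots.iterrows():
        area = math.pi * float(p["radius"]) ** 2
        rows.append(aggregate_plot(trees, p["plot_id"], area, params, dbh_summary))
        rows[-1]["site"] = p.get("site", "")
    return pd.DataFrame(rows).set_index("plot_id")


def attach_wood_density(
    trees: pd.DataFrame,
    density_table: pd.DataFrame,
    allow_mean_fallback: bool = False,
) -> pd.DataFrame:
    """Add a ``wood_density`` column to a tree table via the lookup rules."""
    dens = [
        lookup_wood_density(s, g, density_table, allow_mean_fallback)
        for s, g in zip(trees["species"], trees["genus"])
    ]
    return trees.assign(wood_density=dens)
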