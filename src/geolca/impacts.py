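"""Spatially explicit impact models applied to pre/post-change landscapes.

Five impact pathways are modelled on raster landscapes:

* **Carbon** — per-cell stock from class carbon densities, optionally
  depressed near forest edges by a saturating-exponential edge profile;
  stock change converted to CO2e at 44/12 and amortized over a fixed
  horizon.
* **Sediment** — gross erosion by the Universal Soil Loss Equation
  (R*K*LS*C*P) and export to streams after downslope vegetative
  retention: each cell's erosion is attenuated by the product of
  ``(1 - retention efficiency)`` over the cells on its D8 flow path.  This
  retention-chain delivery is a deliberately simple, monotone variant of
  connectivity-index delivery-ratio models: it preserves the property the
  analysis hinges on, that removing a vegetated buffer between a source
  cell and the stream increases export.
* **Nitrogen** — class-based surface loads (plus any intensification
  loads) routed through the same retention chain.
* **Blue water** — irrigation consumption as the crop-water deficit
  ``max(0, Kc*ET0 - effective precipitation)`` on irrigated agricultural
  cells, plus any intensification irrigation; 1 mm over 1 ha = 10 m3.
* **Biodiversity** — mean species abundance (MSA) per cell as the product
  of a land-use term MSA_LU and, on natural cells, a fragmentation term
  MSA_F that increases with the 8-connected patch area; damage is the
  MSA-weighted area lost between two landscapes, which automatically
  captures losses on unconverted land whose patch shrank or split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .classes import LulcClassTable
from .raster import Grid
from .terrain import TerrainBundle, path_attenuation

__all__ = [
    "EdgeParams",
    "FragTable",
    "IntensificationResponse",
    "carbon_stock",
    "carbon_change",
    "usle",
    "sediment_export",
    "nitrogen_export",
    "intensification_inputs",
    "blue_water",
    "msa_map",
    "biodiversity_damage",
]

CO2_PER_C = 44.0 / 12.0


@dataclass(frozen=True)
class EdgeParams:
    """Forest-edge carbon depression.

    At distance ``d`` (metres) from the nearest non-forest cell, a forest
    cell holds ``carbon_density * (theta + (1 - theta) * (1 - exp(-d/d0)))``
    — a fraction ``interior_fraction_at_edge`` (theta) at the edge, rising
    to the full interior density with e-folding distance ``d0``.
    """

    enabled: bool = False
    interior_fraction_at_edge: float = 0.6
    e_fold_distance: float = 500.0  # metres

    def __post_init__(self) -> None:
        if not 0.0 < self.interior_fraction_at_edge <= 1.0:
            raise ValueError("interior_fraction_at_edge must lie in (0, 1]")
        if self.e_fold_distance <= 0:
            raise ValueError("e_fold_distance must be positive")


@dataclass(frozen=True)
class FragTable:
    """Patch-area -> fragmentation multiplier (MSA_F) lookup.

    ``thresholds`` are ascending patch-area upper bounds in hectares;
    ``multipliers`` the MSA_F applying to patches up to that bound, and
    must be non-decreasing.  Patches larger than the last threshold get
    multiplier 1.  Default values are plausible placeholders, not sourced
    estimates.
    """

    thresholds: tuple[float, ...] = (10.0, 100.0, 1_000.0, 10_000.0)
    multipliers: tuple[float, ...] = (0.55, 0.70, 0.85, 0.95)

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.multipliers):
            raise ValueError("thresholds and multipliers must have equal length")
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("thresholds must be ascending")
        m = self.multipliers
        if any(b < a for a, b in zip(m, m[1:])) or any(not 0 < v <= 1 for v in m):
            raise ValueError("multipliers must be non-decreasing and in (0, 1]")

    def multiplier(self, area_ha: float) -> float:
        for t, m in zip(self.thresholds, self.multipliers):
            if area_ha <= t:
                return m
        return 1.0


@dataclass(frozen=True)
class IntensificationResponse:
    """Linear input-response of yields to nitrogen and irrigation.

    ``slope_n``: added N application (kg N/ha) per t/ha of yield increment;
    ``leach_fraction``: share of applied N leached to the surface load;
    ``slope_w``: added irrigation (mm) per t/ha of yield increment.
    """

    slope_n: float = 20.0
    leach_fraction: float = 0.25
    slope_w: float = 30.0


# ---------------------------------------------------------------------------
# carbon


def carbon_stock(lulc: Grid, table: LulcClassTable, edge: EdgeParams | None = None) -> Grid:
    """Per-cell carbon density (t C/ha), with optional forest-edge depression."""
    codes = lulc.values.astype(int)
    density = table.map_values(np.where(lulc.valid, codes, -1), "carbon_density")
    if edge is not None and edge.enabled:
        forest = (codes == table.code_of("forest")) & lulc.valid
        if forest.any():
            # distance (m) from each forest cell to the nearest non-forest cell
            d = ndimage.distance_transform_edt(forest) * lulc.cell_size
            theta = edge.interior_fraction_at_edge
            factor = theta + (1.0 - theta) * (1.0 - np.exp(-d / edge.e_fold_distance))
            density = np.where(forest, density * factor, density)
    density[~lulc.valid] = np.nan
    return lulc.like(density, nodata=np.nan)


def carbon_change(
    stock_before: Grid, stock_after: Grid, amortization_years: float = 20.0
) -> dict[str, float]:
    """Total carbon loss, as t C, t CO2e, and amortized t CO2e/yr."""
    if not stock_before.same_georef(stock_after):
        raise ValueError("stock grids are not co-registered")
    valid = stock_before.valid & stock_after.valid
    delta = np.where(valid, stock_before.values - stock_after.values, 0.0)
    tonnes_c = float(delta.sum() * stock_before.cell_area_ha)
    co2e = tonnes_c * CO2_PER_C
    return {
        "tonnes_c": tonnes_c,
        "tonnes_co2e": co2e,
        "tonnes_co2e_per_year": co2e / amortization_years,
    }


# ---------------------------------------------------------------------------
# sediment


def usle(
    erosivity: Grid, erodibility: Grid, slope_ls: Grid, lulc: Grid, table: LulcClassTable
) -> Grid:
    """Gross erosion R*K*LS*C*P in t/ha/yr."""
    for name, g in (("erodibility", erodibility), ("slope_ls", slope_ls), ("lulc", lulc)):
        if not erosivity.same_georef(g):
            raise ValueError(f"USLE factor grid {name!r} is not co-registered")
    codes = lulc.values.astype(int)
    c = table.map_values(np.where(lulc.valid, codes, -1), "usle_c")
    p = table.map_values(np.where(lulc.valid, codes, -1), "usle_p")
    valid = erosivity.valid & erodibility.valid & slope_ls.valid & lulc.valid
    out = np.where(valid, erosivity.values * erodibility.values * slope_ls.values * c * p, np.nan)
    return lulc.like(out, nodata=np.nan)


def sediment_export(
    usle_grid: Grid, terrain: TerrainBundle, lulc: Grid, table: LulcClassTable
) -> tuple[Grid, float]:
    """Sediment reaching streams after downslope retention; (grid, total t/yr)."""
    if not usle_grid.same_georef(lulc):
        raise ValueError("usle and lulc grids are not co-registered")
    codes = lulc.values.astype(int)
    retention = table.map_values(np.where(lulc.valid, codes, -1), "sed_retention_eff", fill=0.0)
    factor = path_attenuation(terrain, retention)
    valid = usle_grid.valid & lulc.valid
    export = np.where(valid, usle_grid.values * factor, np.nan)
    total = float(np.nansum(np.where(valid, export, 0.0)) * usle_grid.cell_area_ha)
    return lulc.like(export, nodata=np.nan), total


# ---------------------------------------------------------------------------
# nitrogen


def nitrogen_export(
    lulc: Grid,
    table: LulcClassTable,
    terrain: TerrainBundle,
    added_load: Grid | None = None,
) -> tuple[Grid, float]:
    """Nitrogen reaching streams: class loads (+ additions) after retention.

    Loads are kg N/ha/yr; the total is kg N/yr.
    """
    codes = lulc.values.astype(int)
    load = table.map_values(np.where(lulc.valid, codes, -1), "n_load", fill=0.0)
    load = np.where(lulc.valid, load, 0.0)
    if added_load is not None:
        if not lulc.same_georef(added_load):
            raise ValueError("added_load grid is not co-registered")
        extra = np.where(added_load.valid, added_load.values, 0.0)
        if extra.min() < 0:
            raise ValueError("added nitrogen loads must be non-negative")
        load = load + extra
    if np.nanmin(load) < 0:
        raise ValueError("nitrogen loads must be non-negative")
    retention = table.map_values(np.where(lulc.valid, codes, -1), "n_retention_eff", fill=0.0)
    factor = path_attenuation(terrain, retention)
    export = np.where(lulc.valid, load * factor, np.nan)
    total = float(np.nansum(np.where(lulc.valid, export, 0.0)) * lulc.cell_area_ha)
    return lulc.like(export, nodata=np.nan), total


def intensification_inputs(
    yield_increment: Grid, response: IntensificationResponse
) -> dict[str, Grid]:
    """Added N application / leached load / irrigation from a yield increment.

    Linear responses: application = slope_n * increment (kg N/ha), leached
    load = application * leach_fraction, irrigation = slope_w * increment
    (mm).  All zero where the increment is zero.
    """
    inc = np.where(yield_increment.valid, yield_increment.values, 0.0)
    if inc.min() < 0:
        raise ValueError("yield increments must be non-negative")
    application = response.slope_n * inc
    return {
        "added_n_application": yield_increment.like(application, nodata=np.nan),
        "added_n_load": yield_increment.like(application * response.leach_fraction, nodata=np.nan),
        "added_irrigation": yield_increment.like(response.slope_w * inc, nodata=np.nan),
    }


# ---------------------------------------------------------------------------
# blue water


def blue_water(
    lulc: Grid,
    table: LulcClassTable,
    et0: Grid,
    precip_eff: Grid,
    irrigated_mask: np.ndarray,
    added_irrigation: Grid | None = None,
) -> tuple[Grid, float]:
    """Irrigation consumption: crop-water deficit on irrigated agriculture.

    Deficit = max(0, Kc*ET0 - effective precipitation) in mm/yr on
    irrigated agricultural cells (zero elsewhere); consumption integrates
    deficit plus any added irrigation over cell areas at 10 m3 per mm*ha.
    Returns (consumption grid in m3, total m3/yr).
    """
    if not lulc.same_georef(et0) or not lulc.same_georef(precip_eff):
        raise ValueError("climate grids are not co-registered with lulc")
    codes = lulc.values.astype(int)
    kc = table.map_values(np.where(lulc.valid, codes, -1), "kc", fill=np.nan)
    ag = table.mask(codes, "is_agriculture") & lulc.valid
    irrigated = ag & np.asarray(irrigated_mask, dtype=bool) & et0.valid & precip_eff.valid
    deficit = np.where(
        irrigated, np.maximum(0.0, kc * et0.values - precip_eff.values), 0.0
    )
    if added_irrigation is not None:
        if not lulc.same_georef(added_irrigation):
            raise ValueError("added_irrigation grid is not co-registered")
        deficit = deficit + np.where(added_irrigation.valid, added_irrigation.values, 0.0)
    m3 = deficit * lulc.cell_area_ha * 10.0  # 1 mm over 1 ha = 10 m3
    m3 = np.where(lulc.valid, m3, np.nan)
    total = float(np.nansum(np.where(lulc.valid, m3, 0.0)))
    return lulc.like(m3, nodata=np.nan), total


# ---------------------------------------------------------------------------
# biodiversity


def msa_map(lulc: Grid, table: LulcClassTable, frag: FragTable | None = None) -> Grid:
    """Per-cell mean species abundance: MSA_LU, times MSA_F on natural cells.

    Natural-class patches are found by 8-connectivity over all natural
    classes jointly; each natural cell's MSA_LU is multiplied by the
    fragmentation multiplier of its patch's area.  Non-natural cells carry
    MSA_LU alone.
    """
    codes = lulc.values.astype(int)
    msa = table.map_values(np.where(lulc.valid, codes, -1), "msa_lu")
    if frag is not None:
        natural = table.mask(codes, "is_natural") & lulc.valid
        if natural.any():
            labels, n = ndimage.label(natural, structure=np.ones((3, 3), dtype=int))
            counts = np.bincount(labels.ravel())
            area = lulc.cell_area_ha
            mult = np.ones(n + 1)
            for lab in range(1, n + 1):
                mult[lab] = frag.multiplier(counts[lab] * area)
            msa = np.where(natural, msa * mult[labels], msa)
    msa[~lulc.valid] = np.nan
    return lulc.like(msa, nodata=np.nan)


def biodiversity_damage(msa_before: Grid, msa_after: Grid) -> float:
    """MSA-weighted area lost between two landscapes (MSA*ha).

    Summed over *all* cells, so patch shrinkage or bisection on
    unconverted land contributes through its fragmentation-multiplier drop.
    """
    if not msa_before.same_georef(msa_after):
        raise ValueError("MSA grids are not co-registered")
    valid = msa_before.valid & msa_after.valid
    delta = np.where(valid, msa_before.values - msa_after.values, 0.0)
    return float(delta.sum() * msa_before.cell_area_ha)
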