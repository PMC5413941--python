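"""LCA integration: the linear comparator branch and the spatial branch.

Two ways of turning a product demand scenario into per-tonne environmental
impacts are computed side by side:

* **Standard branch** — the conventional attributional treatment: every
  impact is a constant per tonne of crop (land-use-change GWP from a
  per-hectare-year factor times a land-occupation factor, erosion and
  biodiversity likewise occupation-based, water and eutrophication from
  per-tonne inventory factors), so per-tonne impacts are volume-invariant
  by construction.
* **Predictive spatial branch** — the land-change model decides *which*
  cells convert; the spatial impact models are run on the landscape before
  and after that change, and their deltas substitute for the agricultural
  stage of the inventory.  Per-tonne impacts then depend on production
  volume whenever suitability, yields or per-cell impacts are spatially
  heterogeneous — which is the point of the comparison.

Carbon from land-use change is amortized over ``amortization_years``
(default 20, the usual PAS2050-style convention) in both branches.
Non-agricultural life-cycle stages (ethanol, ethylene, polymerization)
enter both branches as identical per-tonne-HDPE constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classes import LulcClassTable
from .demand import DemandScenario, SupplyPartition, crop_demand, intensification_supply, partition_demand
from .impacts import (
    EdgeParams,
    FragTable,
    IntensificationResponse,
    biodiversity_damage,
    blue_water,
    carbon_change,
    carbon_stock,
    intensification_inputs,
    msa_map,
    nitrogen_export,
    sediment_export,
    usle,
)
from .landchange import (
    ChangeMap,
    allocate_expansion,
    fit_suitability,
    observed_change,
    predict_suitability,
    proximity_allocate,
)
from .raster import Grid
from .synth import LandscapeBundle
from .terrain import TerrainBundle, derive_terrain

__all__ = [
    "CATEGORIES",
    "StandardFactors",
    "ImpactResult",
    "ParamRange",
    "ImpactModelConfig",
    "derive_usle_factors",
    "apply_change",
    "standard_lca",
    "luci_lca",
    "relative_difference",
    "scenario_sweep",
    "sensitivity_envelope",
    "validate_against_observed",
    "matched_standard_factors",
]

#: impact categories and their units
CATEGORIES: tuple[str, ...] = ("gwp", "eutrophication", "water", "erosion", "biodiversity")
UNITS: dict[str, str] = {
    "gwp": "t CO2e",
    "eutrophication": "kg N-eq",
    "water": "m3",
    "erosion": "t sediment",
    "biodiversity": "MSA-ha",
}


@dataclass(frozen=True)
class StandardFactors:
    """Constant characterization factors of the standard branch.

    ``luc_gwp_factor`` is in t CO2e per hectare per year (e.g. 10.81 for a
    sugarcane-type system, 0.02 for a maize-type one, from direct
    land-use-change accounting); ``land_occupation`` in ha*yr per tonne of
    crop; the remaining agricultural-stage factors per hectare or per tonne
    of crop as named.  ``non_ag_stage_impacts`` are per-tonne-HDPE
    constants for everything outside the agricultural stage.
    """

    luc_gwp_factor: float = 0.02
    land_occupation: float = 0.11  # ha*yr per t crop (~9 t/ha yield)
    pnv_msa: float = 0.95
    current_msa: float = 0.30
    erosion_per_ha: float = 5.0  # t/ha/yr
    water_per_tonne: float = 60.0  # m3 per t crop
    eutroph_per_tonne: float = 2.5  # kg N per t crop
    non_ag_stage_impacts: Mapping[str, float] = field(
        default_factory=lambda: {
            "gwp": 2.0, "eutrophication": 0.5, "water": 5.0,
            "erosion": 0.0, "biodiversity": 0.0,
        }
    )

    def __post_init__(self) -> None:
        for name in ("luc_gwp_factor", "land_occupation", "erosion_per_ha",
                     "water_per_tonne", "eutroph_per_tonne"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class ImpactResult:
    """Per-category totals and per-tonne-HDPE impacts for one method run."""

    method_label: str
    hdpe_tonnes: float
    per_tonne: dict[str, float]
    totals: dict[str, float]

    @classmethod
    def from_per_tonne(cls, method: str, volume: float, per_tonne: Mapping[str, float]) -> "ImpactResult":
        pt = {k: float(per_tonne[k]) for k in CATEGORIES}
        return cls(method, volume, pt, {k: pt[k] * volume for k in CATEGORIES})

    @classmethod
    def from_totals(cls, method: str, volume: float, totals: Mapping[str, float]) -> "ImpactResult":
        tot = {k: float(totals[k]) for k in CATEGORIES}
        pt = {k: (tot[k] / volume if volume > 0 else 0.0) for k in CATEGORIES}
        return cls(method, volume, pt, tot)

    def check(self, rtol: float = 1e-6) -> None:
        for k in CATEGORIES:
            expect = self.per_tonne[k] * self.hdpe_tonnes
            if abs(expect - self.totals[k]) > rtol * max(1.0, abs(self.totals[k])):
                raise AssertionError(f"per_tonne x volume != total for {k}")


@dataclass(frozen=True)
class ParamRange:
    """A sensitivity range low <= central <= high for one named parameter."""

    parameter: str
    low: float
    central: float
    high: float

    def __post_init__(self) -> None:
        if not self.low <= self.central <= self.high:
            raise ValueError(f"{self.parameter}: range must satisfy low <= central <= high")


@dataclass(frozen=True)
class ImpactModelConfig:
    """Knobs of the spatial impact models used by the predictive branch."""

    edge: EdgeParams = field(default_factory=EdgeParams)
    frag: FragTable = field(default_factory=FragTable)
    response: IntensificationResponse = field(default_factory=IntensificationResponse)
    amortization_years: float = 20.0
    fert_gwp_per_kg_n: float = 5.6e-3  # t CO2e per kg N applied
    erosivity_per_mm: float = 0.5  # rainfall-erosivity proxy: R = coeff * precip
    effective_precip_fraction: float = 0.7
    irrigate_new_agriculture: bool = True
    stream_threshold: int = 50
    non_ag_stage_impacts: Mapping[str, float] = field(
        default_factory=lambda: {
            "gwp": 2.0, "eutrophication": 0.5, "water": 5.0,
            "erosion": 0.0, "biodiversity": 0.0,
        }
    )


# ---------------------------------------------------------------------------
# helpers shared by the spatial branch


def derive_usle_factors(bundle: LandscapeBundle, terrain: TerrainBundle,
                        config: ImpactModelConfig) -> tuple[Grid, Grid, Grid]:
    """(R, K, LS) factor grids from the landscape's climate, soils, terrain.

    R is a linear rainfall-erosivity proxy; K a texture/organic-matter
    regression surrogate clipped to a plausible band; LS the classic
    quadratic slope-percent approximation for a standard slope length.
    """
    precip = bundle.precip
    r = precip.like(config.erosivity_per_mm * precip.values)
    silt, som = bundle.silt.values, bundle.som.values
    k = np.clip(0.1 + 0.003 * silt + 0.02 * (1.0 - np.minimum(som, 10.0) / 10.0), 0.02, 0.65)
    k_grid = bundle.silt.like(k)
    s_pct = np.tan(np.radians(np.where(terrain.slope.valid, terrain.slope.values, 0.0))) * 100.0
    ls = 0.065 + 0.0456 * s_pct + 0.0065 * s_pct**2
    ls_grid = bundle.dem.like(ls)
    return r, k_grid, ls_grid


def apply_change(lulc: Grid, change_map: ChangeMap, class_table: LulcClassTable) -> Grid:
    """Post-change land cover: converted cells become the agriculture class."""
    ag_code = class_table.code_of("agriculture")
    out = lulc.values.copy()
    out[change_map.mask] = ag_code
    return lulc.like(out)


# ---------------------------------------------------------------------------
# standard branch


def standard_lca(scenario: DemandScenario, factors: StandardFactors) -> ImpactResult:
    """Linear, volume-invariant LCA: constant per-tonne impacts.

    Agricultural-stage impacts per tonne of crop come from occupation- and
    inventory-based factors; they are scaled to per tonne of HDPE through
    the conversion chain and topped with the non-agricultural stage
    constants.  Per-tonne values are independent of the scenario volume by
    construction.
    """
    cph = scenario.chain.crop_per_hdpe
    occ = factors.land_occupation
    per_tonne_crop = {
        "gwp": factors.luc_gwp_factor * occ,
        "erosion": factors.erosion_per_ha * occ,
        "biodiversity": (factors.pnv_msa - factors.current_msa) * occ,
        "water": factors.water_per_tonne,
        "eutrophication": factors.eutroph_per_tonne,
    }
    per_tonne = {
        k: per_tonne_crop[k] * cph + factors.non_ag_stage_impacts.get(k, 0.0)
        for k in CATEGORIES
    }
    return ImpactResult.from_per_tonne("standard", scenario.hdpe_tonnes, per_tonne)


# ---------------------------------------------------------------------------
# predictive spatial branch


def luci_lca(
    change_map: ChangeMap,
    partition: SupplyPartition,
    landscape: LandscapeBundle,
    scenario: DemandScenario,
    config: ImpactModelConfig | None = None,
    terrain: TerrainBundle | None = None,
) -> ImpactResult:
    """Spatial-model substitution into the agricultural stage.

    Runs every impact model on the landscape before and after the change
    map (plus intensification), and uses the deltas as the agricultural
    stage of the inventory:

    * GWP: amortized CO2e from the carbon-stock change, plus fertilizer
      production for intensification nitrogen;
    * eutrophication: change in nitrogen export, including intensification
      loads;
    * erosion: change in sediment export (delivery after retention);
    * water: irrigation consumption on new plus intensified agriculture;
    * biodiversity: MSA-weighted area lost, fragmentation included.

    Non-agricultural stages enter as per-tonne constants.  The supplied
    change map and partition must together meet the scenario's crop demand
    to within one cell's production.
    """
    config = config or ImpactModelConfig()
    table = landscape.class_table
    demand = crop_demand(scenario)
    supplied = change_map.total_production + partition.intensification_supply
    area = landscape.lulc.cell_area_ha
    one_cell = float(np.nanmax(np.where(landscape.yield_current.valid,
                                        landscape.yield_current.values, 0.0))) * area
    if abs(supplied - demand) > one_cell + 1e-6:
        raise ValueError(
            f"supplied production {supplied:.3f} t does not meet crop demand "
            f"{demand:.3f} t within one-cell tolerance {one_cell:.3f} t"
        )
    if scenario.hdpe_tonnes == 0:
        return ImpactResult.from_per_tonne("luci", 0.0, {k: 0.0 for k in CATEGORIES})

    lulc0 = landscape.lulc
    lulc1 = apply_change(lulc0, change_map, table)
    if terrain is None:
        terrain = derive_terrain(landscape.dem, stream_threshold=config.stream_threshold)

    # carbon
    stock0 = carbon_stock(lulc0, table, config.edge)
    stock1 = carbon_stock(lulc1, table, config.edge)
    cc = carbon_change(stock0, stock1, config.amortization_years)

    # sediment
    r, k, ls = derive_usle_factors(landscape, terrain, config)
    _, sed0 = sediment_export(usle(r, k, ls, lulc0, table), terrain, lulc0, table)
    _, sed1 = sediment_export(usle(r, k, ls, lulc1, table), terrain, lulc1, table)

    # nitrogen, with intensification loads on the post landscape
    adds = intensification_inputs(partition.yield_increment, config.response)
    _, n0 = nitrogen_export(lulc0, table, terrain)
    _, n1 = nitrogen_export(lulc1, table, terrain, added_load=adds["added_n_load"])

    # blue water: new agriculture (if irrigated) plus intensification irrigation
    irrigated = change_map.mask if config.irrigate_new_agriculture else np.zeros(lulc0.shape, bool)
    precip_eff = landscape.precip.like(config.effective_precip_fraction * landscape.precip.values)
    _, water_total = blue_water(lulc1, table, landscape.et0, precip_eff,
                                irrigated, added_irrigation=adds["added_irrigation"])

    # biodiversity
    msa0 = msa_map(lulc0, table, config.frag)
    msa1 = msa_map(lulc1, table, config.frag)
    bio = biodiversity_damage(msa0, msa1)

    added_n_kg = float(np.nansum(adds["added_n_application"].values) * area)
    volume = scenario.hdpe_tonnes
    totals = {
        "gwp": cc["tonnes_co2e_per_year"] + config.fert_gwp_per_kg_n * added_n_kg
        + config.non_ag_stage_impacts.get("gwp", 0.0) * volume,
        "eutrophication": (n1 - n0) + config.non_ag_stage_impacts.get("eutrophication", 0.0) * volume,
        "erosion": (sed1 - sed0) + config.non_ag_stage_impacts.get("erosion", 0.0) * volume,
        "water": water_total + config.non_ag_stage_impacts.get("water", 0.0) * volume,
        "biodiversity": bio + config.non_ag_stage_impacts.get("biodiversity", 0.0) * volume,
    }
    return ImpactResult.from_totals("luci", volume, totals)


def relative_difference(impact_a: float, impact_b: float) -> float:
    """Signed percent by which ``impact_a`` exceeds ``impact_b``."""
    if impact_b == 0:
        raise ZeroDivisionError("reference impact is zero")
    return 100.0 * (impact_a - impact_b) / impact_b


# ---------------------------------------------------------------------------
# orchestration


def run_scenario(
    landscape: LandscapeBundle,
    scenario: DemandScenario,
    factors: StandardFactors,
    config: ImpactModelConfig | None = None,
    allocator: str = "logistic",
    suitability: Grid | None = None,
    terrain: TerrainBundle | None = None,
) -> tuple[ImpactResult, ImpactResult, ChangeMap, SupplyPartition]:
    """One end-to-end run: partition demand, allocate expansion, both branches."""
    config = config or ImpactModelConfig()
    table = landscape.class_table
    demand = crop_demand(scenario)
    supply, increment = intensification_supply(
        landscape.yield_current, landscape.yield_attainable,
        landscape.ag_mask, scenario.closure_fraction,
    )
    partition = partition_demand(demand, increment)
    if allocator == "logistic":
        if suitability is None:
            model = fit_suitability(
                landscape.lulc.like((landscape.ag_mask).astype(float)),
                landscape.predictors(),
                exclusion_mask=~table.mask(landscape.lulc.values.astype(int), "convertible")
                & ~landscape.ag_mask,
            )
            suitability = predict_suitability(model, landscape.predictors())
        change = allocate_expansion(suitability, landscape.lulc, table,
                                    landscape.yield_current, partition.expansion_demand)
    elif allocator == "proximity":
        change = proximity_allocate(landscape.lulc, table,
                                    landscape.yield_current, partition.expansion_demand)
    else:
        raise ValueError(f"unknown allocator {allocator!r}")
    std = standard_lca(scenario, factors)
    luci = luci_lca(change, partition, landscape, scenario, config, terrain=terrain)
    return std, luci, change, partition


def scenario_sweep(
    volumes: Sequence[float],
    landscape: LandscapeBundle,
    factors: StandardFactors,
    config: ImpactModelConfig | None = None,
    chain=None,
    closure_fraction: float = 0.2,
    allocator: str = "logistic",
) -> list[tuple[float, ImpactResult, ImpactResult]]:
    """Both branches across increasing production volumes.

    The suitability model is fitted once; the standard branch's per-tonne
    impacts are flat across volumes while the spatial branch's vary with
    landscape heterogeneity.
    """
    from .demand import ConversionChain

    if list(volumes) != sorted(volumes) or min(volumes) <= 0:
        raise ValueError("volumes must be positive and increasing")
    chain = chain or ConversionChain()
    config = config or ImpactModelConfig()
    table = landscape.class_table
    model = fit_suitability(
        landscape.lulc.like((landscape.ag_mask).astype(float)),
        landscape.predictors(),
        exclusion_mask=~table.mask(landscape.lulc.values.astype(int), "convertible")
        & ~landscape.ag_mask,
    )
    suitability = predict_suitability(model, landscape.predictors())
    terrain = derive_terrain(landscape.dem, stream_threshold=config.stream_threshold)
    out = []
    for v in volumes:
        scenario = DemandScenario(v, chain=chain, closure_fraction=closure_fraction)
        std, luci, _, _ = run_scenario(
            landscape, scenario, factors, config,
            allocator=allocator, suitability=suitability, terrain=terrain,
        )
        out.append((float(v), std, luci))
    return out


def sensitivity_envelope(
    ranges: Sequence[ParamRange],
    evaluate: Callable[[Mapping[str, float]], Mapping[str, float]],
    categories: Sequence[str] = CATEGORIES,
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """Two-corner sensitivity bounds around a central pipeline evaluation.

    ``evaluate`` maps parameter overrides (name -> value) to per-category
    impact values.  For each category the monotone direction of every
    parameter is probed one-at-a-time, then the category's low/high corner
    (each parameter at the bound pulling that category down/up) is
    evaluated.  For models monotone in each parameter this equals the full
    2^k corner enumeration.  Returns ``(low, high, central)`` dicts.
    """
    cache: dict[tuple, dict[str, float]] = {}

    def run(assign: Mapping[str, float]) -> dict[str, float]:
        key = tuple(sorted(assign.items()))
        if key not in cache:
            cache[key] = {k: float(v) for k, v in evaluate(assign).items()}
        return cache[key]

    central_assign = {r.parameter: r.central for r in ranges}
    central = run(central_assign)

    # probe the direction of each parameter for each category
    rising: dict[str, dict[str, bool]] = {}
    for r in ranges:
        probe = dict(central_assign)
        probe[r.parameter] = r.high
        res = run(probe)
        rising[r.parameter] = {k: res[k] >= central[k] for k in categories}

    low, high = {}, {}
    for k in categories:
        lo_assign = {r.parameter: (r.low if rising[r.parameter][k] else r.high) for r in ranges}
        hi_assign = {r.parameter: (r.high if rising[r.parameter][k] else r.low) for r in ranges}
        low[k] = run(lo_assign)[k]
        high[k] = run(hi_assign)[k]
        lo, hi = min(low[k], high[k]), max(low[k], high[k])
        low[k], high[k] = lo, hi
    return low, high, central


def validate_against_observed(
    lulc_t0: Grid,
    lulc_t1: Grid,
    landscape: LandscapeBundle,
    factors: StandardFactors,
    config: ImpactModelConfig | None = None,
    chain=None,
) -> pd.DataFrame:
    """Compare modelled allocations against observed conversion.

    The observed t0 -> t1 conversion defines the demand (its production
    volume); the logistic and proximity allocators are then run at that
    same volume on the t0 landscape, and per-tonne impacts of all three
    change maps are tabulated with ratios to the observed branch.
    """
    from .demand import ConversionChain

    config = config or ImpactModelConfig()
    chain = chain or ConversionChain()
    table = landscape.class_table
    base = replace(landscape, lulc=lulc_t0) if landscape.lulc is not lulc_t0 else landscape

    observed = observed_change(lulc_t0, lulc_t1, table, base.yield_current)
    if observed.n_cells == 0:
        raise ValueError("no observed conversion between the two snapshots")
    production = observed.total_production
    hdpe = production / chain.crop_per_hdpe
    scenario = DemandScenario(hdpe, chain=chain, closure_fraction=0.0)
    empty_partition = partition_demand(0.0, base.yield_current.like(
        np.zeros(base.yield_current.shape)))
    # all demand goes to expansion
    empty_partition = SupplyPartition(
        total_crop_demand=production, intensification_supply=0.0,
        expansion_demand=production, yield_increment=empty_partition.yield_increment,
    )
    terrain = derive_terrain(base.dem, stream_threshold=config.stream_threshold)

    ag0 = table.mask(lulc_t0.values.astype(int), "is_agriculture") & lulc_t0.valid
    model = fit_suitability(
        lulc_t0.like(ag0.astype(float)),
        base.predictors(),
        exclusion_mask=~table.mask(lulc_t0.values.astype(int), "convertible") & ~ag0,
    )
    suit = predict_suitability(model, base.predictors())
    logistic = allocate_expansion(suit, lulc_t0, table, base.yield_current, production)
    proximity = proximity_allocate(lulc_t0, table, base.yield_current, production)

    results = {}
    for label, cm in (("observed", observed), ("logistic", logistic), ("proximity", proximity)):
        res = luci_lca(cm, empty_partition, base, scenario, config, terrain=terrain)
        results[label] = res.per_tonne
    rows = []
    for k in CATEGORIES:
        obs = results["observed"][k]
        rows.append({
            "category": k,
            "unit": f"{UNITS[k]} per t HDPE",
            "observed": obs,
            "logistic": results["logistic"][k],
            "proximity": results["proximity"][k],
            "ratio_logistic": results["logistic"][k] / obs if obs != 0 else np.nan,
            "ratio_proximity": results["proximity"][k] / obs if obs != 0 else np.nan,
        })
    return pd.DataFrame(rows).set_index("category")


# ---------------------------------------------------------------------------
# degeneracy bridge


def matched_standard_factors(
    landscape: LandscapeBundle,
    source_class: str,
    config: ImpactModelConfig,
    terrain: TerrainBundle | None = None,
) -> StandardFactors:
    """Standard-branch factors matched to a *homogeneous* landscape.

    On a landscape with uniform yields, climate, soils and a single
    convertible source class — and with retention efficiencies, edge
    effects and fragmentation switched off — the spatial models produce
    the same per-hectare impact on every converted cell.  This computes
    the per-hectare/per-tonne factors analytically from the class table
    so that the standard and spatial branches must agree; any residual
    difference between the branches is then attributable to spatial
    heterogeneity alone.
    """
    table = landscape.class_table
    ag = table.code_of("agriculture")
    src = table.code_of(source_class)
    y = float(np.median(landscape.yield_current.values))
    occupation = 1.0 / y

    d_carbon = table.param(src, "carbon_density") - table.param(ag, "carbon_density")
    luc_gwp = d_carbon * (44.0 / 12.0) / config.amortization_years  # t CO2e/ha/yr

    if terrain is None:
        terrain = derive_terrain(landscape.dem, stream_threshold=config.stream_threshold)
    r, k, ls = derive_usle_factors(landscape, terrain, config)
    rkls = float(np.median(r.values * k.values * ls.values))
    d_usle = rkls * (
        table.param(ag, "usle_c") * table.param(ag, "usle_p")
        - table.param(src, "usle_c") * table.param(src, "usle_p")
    )

    d_nload = table.param(ag, "n_load") - table.param(src, "n_load")

    kc = table.param(ag, "kc")
    et0 = float(np.median(landscape.et0.values))
    pe = config.effective_precip_fraction * float(np.median(landscape.precip.values))
    deficit = max(0.0, kc * et0 - pe) if config.irrigate_new_agriculture else 0.0

    return StandardFactors(
        luc_gwp_factor=luc_gwp,
        land_occupation=occupation,
        pnv_msa=table.param(src, "msa_lu"),
        current_msa=table.param(ag, "msa_lu"),
        erosion_per_ha=d_usle,
        water_per_tonne=deficit * 10.0 / y,
        eutroph_per_tonne=d_nload / y,
        non_ag_stage_impacts=dict(config.non_ag_stage_impacts),
    )
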