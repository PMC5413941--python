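"""Demand scenarios: from product tonnage to crop demand, and its partition
between intensification and expansion.

A bio-based HDPE demand is propagated through the feedstock conversion
chain (HDPE -> ethylene -> ethanol -> crop) to a crop-production demand in
tonnes.  Part of that demand can be met by *intensification* — closing a
fraction of the yield gap on existing agricultural land — and the remainder
becomes *expansion demand*, to be met by converting new land.

The default scenario volumes are 23,000, 86,000 and 321,000 tonnes of HDPE,
spanning single-company to sector-scale demand.  The conversion-chain
defaults are round placeholder values for an ethanol-to-ethylene route and
should be replaced with inventory-sourced factors for real analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .raster import Grid

__all__ = [
    "ConversionChain",
    "DemandScenario",
    "SupplyPartition",
    "DEFAULT_VOLUMES",
    "default_scenarios",
    "crop_demand",
    "intensification_supply",
    "partition_demand",
]

#: default HDPE scenario volumes, tonnes
DEFAULT_VOLUMES: tuple[float, ...] = (23_000.0, 86_000.0, 321_000.0)


@dataclass(frozen=True)
class ConversionChain:
    """Mass conversion factors along HDPE -> ethylene -> ethanol -> crop.

    All factors are tonnes of input per tonne of output of that step.
    Placeholder defaults; not inventory-authoritative.
    """

    ethylene_per_hdpe: float = 1.0
    ethanol_per_ethylene: float = 1.74
    crop_per_ethanol: float = 3.0

    def __post_init__(self) -> None:
        if min(self.ethylene_per_hdpe, self.ethanol_per_ethylene, self.crop_per_ethanol) <= 0:
            raise ValueError("conversion factors must be positive")

    @property
    def crop_per_hdpe(self) -> float:
        return self.ethylene_per_hdpe * self.ethanol_per_ethylene * self.crop_per_ethanol


@dataclass(frozen=True)
class DemandScenario:
    hdpe_tonnes: float
    chain: ConversionChain = field(default_factory=ConversionChain)
    closure_fraction: float = 0.2  # fraction of the yield gap closed on existing ag
    feedstock_label: str = "maize"

    def __post_init__(self) -> None:
        if self.hdpe_tonnes < 0:
            raise ValueError("hdpe_tonnes must be >= 0")
        if not 0.0 <= self.closure_fraction <= 1.0:
            raise ValueError("closure_fraction must lie in [0, 1]")


@dataclass
class SupplyPartition:
    """How total crop demand splits between intensification and expansion.

    ``yield_increment`` holds the per-pixel yield increase (t/ha) actually
    credited to intensification (after any trimming); conservation
    ``intensification_supply + expansion_demand == total_crop_demand``
    holds to 1e-6 t.
    """

    total_crop_demand: float
    intensification_supply: float
    expansion_demand: float
    yield_increment: Grid

    def check(self, tol: float = 1e-6) -> None:
        gap = abs(self.intensification_supply + self.expansion_demand - self.total_crop_demand)
        if gap > tol:
            raise AssertionError(f"partition violates conservation by {gap} t")


def default_scenarios(
    chain: ConversionChain | None = None,
    closure_fraction: float = 0.2,
    feedstock_label: str = "maize",
) -> list[DemandScenario]:
    """The three shipped demand scenarios (23k, 86k, 321k t HDPE)."""
    chain = chain or ConversionChain()
    return [
        DemandScenario(v, chain=chain, closure_fraction=closure_fraction,
                       feedstock_label=feedstock_label)
        for v in DEFAULT_VOLUMES
    ]


def crop_demand(scenario: DemandScenario) -> float:
    """Crop tonnage needed to supply the scenario's HDPE tonnage."""
    return scenario.hdpe_tonnes * scenario.chain.crop_per_hdpe


def intensification_supply(
    yield_current: Grid,
    yield_attainable: Grid,
    ag_mask: np.ndarray,
    closure_fraction: float,
) -> tuple[float, Grid]:
    """Supply available from partial yield-gap closure on existing agriculture.

    Per agricultural cell the yield increment is
    ``closure_fraction * max(0, attainable - current)`` (t/ha); the supply
    is the increment integrated over cell areas.
    """
    if not yield_current.same_georef(yield_attainable):
        raise ValueError("yield grids are not co-registered")
    if not 0.0 <= closure_fraction <= 1.0:
        raise ValueError("closure_fraction must lie in [0, 1]")
    valid = yield_current.valid & yield_attainable.valid & np.asarray(ag_mask, dtype=bool)
    gap = np.maximum(0.0, yield_attainable.values - yield_current.values)
    increment = np.where(valid, closure_fraction * gap, 0.0)
    supply = float(increment.sum() * yield_current.cell_area_ha)
    return supply, yield_current.like(increment, nodata=np.nan)


def partition_demand(total_crop_demand: float, increment: Grid) -> SupplyPartition:
    """Split demand: intensification fills first, the remainder is expansion.

    When intensification capacity exceeds demand, intensified cells are
    trimmed deterministically largest-gap-first: cells are credited in
    descending increment order (row-major index breaking ties) and the
    marginal cell is scaled so that supply equals demand exactly.
    """
    if total_crop_demand < 0:
        raise ValueError("total_crop_demand must be >= 0")
    area = increment.cell_area_ha
    inc = np.maximum(increment.values, 0.0)
    capacity = float(inc.sum() * area)

    if capacity <= total_crop_demand:
        used = inc
        supply = capacity
    else:
        flat = inc.ravel()
        order = np.lexsort((np.arange(flat.size), -flat))  # largest gap first
        cum = np.cumsum(flat[order] * area)
        k = int(np.searchsorted(cum, total_crop_demand, side="left"))
        used_flat = np.zeros_like(flat)
        used_flat[order[:k]] = flat[order[:k]]
        already = cum[k - 1] if k > 0 else 0.0
        # partial credit on the marginal cell closes the balance exactly
        used_flat[order[k]] = (total_crop_demand - already) / area
        used = used_flat.reshape(inc.shape)
        supply = total_crop_demand
    return SupplyPartition(
        total_crop_demand=total_crop_demand,
        intensification_supply=supply,
        expansion_demand=total_crop_demand - supply,
        yield_increment=increment.like(used, nodata=np.nan),
    )
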