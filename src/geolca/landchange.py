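"""Land-change modelling: where does agricultural expansion happen?

The primary allocator fits a logistic suitability model to current
agriculture occurrence (a binary response on standardized soil/terrain
predictors, maximum-likelihood fit), predicts a per-pixel conversion
probability, and converts the highest-suitability convertible cells in
rank order until their cumulative production meets the expansion demand.
Demand is expressed in production (tonnes), not area, so a spatially
varying yield map makes expansion area an output of the allocation.

Two alternatives support validation: a frontier-proximity allocator that
ranks cells by Euclidean distance to existing agriculture, and extraction
of the observed conversion between two land-cover snapshots.

Cells whose class is not convertible (urban, barren, water) are never
converted and are excluded from the regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import ndimage

from .classes import LulcClassTable
from .raster import Grid, GridStack

__all__ = [
    "SuitabilityModel",
    "ChangeMap",
    "fit_suitability",
    "predict_suitability",
    "allocate_expansion",
    "proximity_allocate",
    "observed_change",
]


@dataclass
class SuitabilityModel:
    """Fitted logistic suitability model on standardized predictors."""

    predictor_names: tuple[str, ...]
    beta: np.ndarray  # intercept first
    standard_errors: np.ndarray
    log_likelihood: float
    n_obs: int
    means: np.ndarray  # fitting-region standardization, reused at prediction
    sds: np.ndarray
    converged: bool = True
    separation_flag: bool = False

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.standard_errors = np.asarray(self.standard_errors, dtype=float)
        if self.beta.size != len(self.predictor_names) + 1:
            raise ValueError("beta must have one coefficient per predictor plus intercept")


@dataclass
class ChangeMap:
    """Pixels converted to agriculture with their assigned yields.

    ``total_production`` integrates ``assigned_yield`` (t/ha) over the
    converted cells' areas; ``source_class`` records each converted cell's
    pre-conversion class code.
    """

    converted: Grid  # binary
    assigned_yield: Grid  # t/ha on converted cells, 0 elsewhere
    source_class: Grid  # pre-conversion code on converted cells, -1 elsewhere
    total_area_ha: float
    total_production: float

    @property
    def mask(self) -> np.ndarray:
        return self.converted.values >= 1

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())


def _standardize(matrix: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    sds = np.where(sds > 0, sds, 1.0)
    return (matrix - means) / sds


def fit_suitability(
    ag_binary: Grid,
    predictors: GridStack,
    exclusion_mask: np.ndarray | None = None,
) -> SuitabilityModel:
    """Maximum-likelihood logistic fit of agriculture occurrence.

    ``exclusion_mask`` marks cells omitted from the regression (classes
    that cannot convert).  Predictors are standardized over the fitting
    region; the means/SDs are stored on the model for prediction-time
    reuse.  Perfect separation is flagged rather than fatal, with the
    diverging coefficients left as fitted.
    """
    if ag_binary.shape != predictors.shape:
        raise ValueError("response and predictor stack are misaligned")
    keep = ag_binary.valid & predictors.valid_all()
    if exclusion_mask is not None:
        keep &= ~np.asarray(exclusion_mask, dtype=bool)
    y = (ag_binary.values[keep] >= 1).astype(float)
    if y.size == 0 or y.min() == y.max():
        raise ValueError("single-class response: both classes must be present after exclusions")

    names = tuple(predictors.names())
    X = np.column_stack([predictors[n].values[keep] for n in names])
    means, sds = X.mean(axis=0), X.std(axis=0)
    # zero-variance predictors carry no information: fit without them and
    # report coefficient 0 with infinite standard error
    informative = sds > 0
    Z = sm.add_constant(_standardize(X, means, sds)[:, informative], has_constant="add")

    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, Z).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises on hard separation
            if "separation" in str(exc).lower():
                res = sm.Logit(y, Z).fit(disp=0, maxiter=200, method="bfgs")
                separation = True
            else:
                raise
        for w in caught:
            if "separation" in str(w.message).lower():
                separation = True
    if separation:
        warnings.warn(
            "perfect separation detected: coefficients may diverge",
            RuntimeWarning, stacklevel=2,
        )
    se_fit = np.asarray(res.bse, dtype=float)
    se_fit = np.where(np.isfinite(se_fit) & (se_fit > 0), se_fit, np.inf)
    beta = np.zeros(len(names) + 1)
    se = np.full(len(names) + 1, np.inf)
    beta[0], se[0] = res.params[0], se_fit[0]
    beta[1:][informative] = np.asarray(res.params, dtype=float)[1:]
    se[1:][informative] = se_fit[1:]
    return SuitabilityModel(
        predictor_names=names,
        beta=beta,
        standard_errors=se,
        log_likelihood=float(res.llf),
        n_obs=int(y.size),
        means=means,
        sds=sds,
        converged=bool(getattr(res, "mle_retvals", {}).get("converged", True)),
        separation_flag=separation,
    )


def predict_suitability(model: SuitabilityModel, predictors: GridStack) -> Grid:
    """Per-cell conversion probability logistic(beta . z); nodata propagated."""
    for name in model.predictor_names:
        if name not in predictors:
            raise KeyError(f"missing predictor grid {name!r}")
    ref = predictors[model.predictor_names[0]]
    valid = predictors.valid_all()
    X = np.column_stack([predictors[n].values[valid] for n in model.predictor_names])
    Z = _standardize(X, model.means, model.sds)
    eta = model.beta[0] + Z @ model.beta[1:]
    prob = np.full(ref.shape, np.nan)
    prob[valid] = 1.0 / (1.0 + np.exp(-eta))
    return ref.like(prob, nodata=np.nan)


def _greedy_allocate(
    suitability_vals: np.ndarray,
    lulc: Grid,
    class_table: LulcClassTable,
    yield_map: Grid,
    expansion_demand: float,
    allocator_label: str,
) -> ChangeMap:
    """Shared greedy rank allocation: descending suitability, row-major ties."""
    if expansion_demand < 0:
        raise ValueError("expansion_demand must be >= 0")
    if not lulc.same_georef(yield_map):
        raise ValueError("lulc and yield grids are not co-registered")
    codes = lulc.values.astype(int)
    convertible = (
        class_table.mask(codes, "convertible")
        & ~class_table.mask(codes, "is_agriculture")
        & lulc.valid
        & yield_map.valid
        & np.isfinite(suitability_vals)
    )
    area = lulc.cell_area_ha
    shape = lulc.shape
    sel = np.zeros(shape, dtype=bool)

    if expansion_demand > 0:
        flat_ok = np.flatnonzero(convertible.ravel())
        suit = suitability_vals.ravel()[flat_ok]
        production = yield_map.values.ravel()[flat_ok] * area
        capacity = float(production.sum())
        if capacity < expansion_demand:
            raise ValueError(
                f"{allocator_label}: expansion demand {expansion_demand:.3f} t exceeds "
                f"convertible capacity {capacity:.3f} t (shortfall "
                f"{expansion_demand - capacity:.3f} t)"
            )
        order = np.lexsort((flat_ok, -suit))  # descending suitability, row-major ties
        cum = np.cumsum(production[order])
        # tolerance keeps an exact-fit demand (e.g. re-running at a change
        # map's own production) from converting one spurious extra cell
        tol = 1e-9 * max(1.0, expansion_demand)
        k = int(np.searchsorted(cum, expansion_demand - tol, side="left")) + 1
        sel.ravel()[flat_ok[order[:k]]] = True

    assigned = np.where(sel, yield_map.values, 0.0)
    source = np.where(sel, codes, -1).astype(float)
    return ChangeMap(
        converted=lulc.like(sel.astype(float), nodata=-1.0),
        assigned_yield=lulc.like(assigned, nodata=np.nan),
        source_class=lulc.like(source, nodata=-1.0),
        total_area_ha=float(sel.sum() * area),
        total_production=float(assigned.sum() * area),
    )


def allocate_expansion(
    suitability: Grid,
    lulc: Grid,
    class_table: LulcClassTable,
    yield_map: Grid,
    expansion_demand: float,
) -> ChangeMap:
    """Convert convertible cells in descending-suitability order.

    Conversion stops at the first cell whose inclusion meets or exceeds the
    demand, so total production lies in
    ``[demand, demand + max single-cell production)``.
    """
    if not suitability.same_georef(lulc):
        raise ValueError("suitability and lulc grids are not co-registered")
    vals = np.where(suitability.valid, suitability.values, np.nan)
    return _greedy_allocate(vals, lulc, class_table, yield_map,
                            expansion_demand, "allocate_expansion")


def proximity_allocate(
    lulc: Grid,
    class_table: LulcClassTable,
    yield_map: Grid,
    expansion_demand: float,
) -> ChangeMap:
    """Frontier-proximity allocator: suitability = -distance to agriculture.

    Ranks convertible cells by Euclidean distance to the nearest current
    agriculture cell (nearest first), with the same exclusions and greedy
    contract as :func:`allocate_expansion`.
    """
    ag = class_table.mask(lulc.values.astype(int), "is_agriculture") & lulc.valid
    if not ag.any():
        raise ValueError("proximity allocation needs at least one agriculture cell")
    dist = ndimage.distance_transform_edt(~ag) * lulc.cell_size
    return _greedy_allocate(-dist, lulc, class_table, yield_map,
                            expansion_demand, "proximity_allocate")


def observed_change(
    lulc_t0: Grid,
    lulc_t1: Grid,
    class_table: LulcClassTable,
    yield_map: Grid,
) -> ChangeMap:
    """Conversion-to-agriculture between two snapshots; abandonment ignored."""
    if not lulc_t0.same_georef(lulc_t1):
        raise ValueError("land-cover snapshots are not co-registered")
    if not lulc_t0.same_georef(yield_map):
        raise ValueError("lulc and yield grids are not co-registered")
    c0 = lulc_t0.values.astype(int)
    c1 = lulc_t1.values.astype(int)
    valid = lulc_t0.valid & lulc_t1.valid
    ag0 = class_table.mask(c0, "is_agriculture")
    ag1 = class_table.mask(c1, "is_agriculture")
    sel = valid & ~ag0 & ag1
    area = lulc_t0.cell_area_ha
    assigned = np.where(sel, yield_map.values, 0.0)
    return ChangeMap(
        converted=lulc_t0.like(sel.astype(float), nodata=-1.0),
        assigned_yield=lulc_t0.like(assigned, nodata=np.nan),
        source_class=lulc_t0.like(np.where(sel, c0, -1).astype(float), nodata=-1.0),
        total_area_ha=float(sel.sum() * area),
        total_production=float(assigned.sum() * area),
    )
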