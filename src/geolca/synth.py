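"""Synthetic landscape generator.

Produces co-registered raster bundles with the statistical structure the
pipeline assumes, so every downstream stage — suitability fitting,
allocation, the spatial impact models, and LCA integration — is testable
without external geodata.  The core contract is that agriculture occurrence
follows a *known* logistic model of standardized soil/terrain predictors,
so the land-change model can be validated by parameter recovery against the
generating process.

Structure of a generated landscape:

* smooth correlated soil fields (pH, %silt, %clay, soil organic matter) and
  climate fields (precipitation, reference evapotranspiration) built from
  Gaussian random fields;
* a tilted, rough DEM that drains to one edge, from which streams are
  derived by flow accumulation;
* agriculture drawn per pixel as Bernoulli(logistic(beta . z)), with z the
  standardized predictor vector and beta the caller-supplied truth;
* remaining cells split into natural classes (forest / savanna / grassland)
  by a second latent field honouring the requested class proportions, with
  urban / water / barren sprinkled at their requested proportions;
* a riparian vegetation class painted over natural cells within a set
  distance of streams (governed by ``riparian_width``, not by
  ``class_proportions``);
* current and attainable crop-yield surfaces increasing with a soil-quality
  index, with attainable >= current everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .classes import CLASS_CODES, LulcClassTable, default_class_table
from .raster import Grid, GridStack, read_grid, write_grid
from .terrain import derive_terrain, slope_degrees

__all__ = [
    "LandscapeParams",
    "LandscapeBundle",
    "gaussian_random_field",
    "generate_landscape",
    "write_landscape",
    "read_landscape",
]

#: predictor grids used (in this order) for the agriculture occurrence model
DEFAULT_PREDICTORS = ("ph", "slope", "silt", "clay", "som")


@dataclass
class LandscapeParams:
    """Knobs of the synthetic landscape generator.

    ``true_beta`` is the coefficient vector (intercept first) of the
    logistic agriculture-occurrence model on standardized predictors, in
    the order of ``predictor_names``.  The realized agriculture fraction is
    therefore governed by ``true_beta`` — the ``agriculture`` entry of
    ``class_proportions`` should be chosen consistently with it (intercept
    ~ logit(fraction) when slopes are moderate).
    """

    shape: tuple[int, int] = (200, 200)
    cell_size: float = 500.0  # matches the coarse land-cover products emulated
    correlation_length: float = 8.0
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "agriculture": 0.35,
            "forest": 0.30,
            "savanna": 0.12,
            "grassland": 0.15,
            "urban": 0.04,
            "water": 0.02,
            "barren": 0.02,
        }
    )
    true_beta: tuple[float, ...] = (-0.62, -0.5, -0.4, 0.35, -0.25, 0.3)
    predictor_names: tuple[str, ...] = DEFAULT_PREDICTORS
    riparian_width: int = 1
    stream_threshold: int = 50
    relief: float = 40.0
    tilt: float = 0.15  # m elevation drop per cell row, gives a south drain
    base_yield: float = 9.0  # t/ha, maize-like
    yield_gap_mean: float = 0.35  # attainable = current * (1 + gap)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_proportions sum to {total}, expected 1")
        if self.correlation_length < 1:
            raise ValueError("correlation_length must be >= 1")
        if len(self.true_beta) != len(self.predictor_names) + 1:
            raise ValueError("true_beta must have one coefficient per predictor plus intercept")


@dataclass
class LandscapeBundle:
    """Co-registered grids plus the class table for one synthetic region."""

    lulc: Grid
    dem: Grid
    ph: Grid
    silt: Grid
    clay: Grid
    som: Grid
    precip: Grid
    et0: Grid
    yield_current: Grid
    yield_attainable: Grid
    class_table: LulcClassTable
    params: LandscapeParams | None = None
    #: per-pixel Bernoulli probability the generator drew agriculture from
    #: (present on generated bundles only; not written to disk)
    true_probability: Grid | None = None

    GRID_NAMES = (
        "lulc", "dem", "ph", "silt", "clay", "som",
        "precip", "et0", "yield_current", "yield_attainable",
    )

    def __post_init__(self) -> None:
        ref = self.lulc
        for name in self.GRID_NAMES:
            if not ref.same_georef(getattr(self, name)):
                raise ValueError(f"grid {name!r} is not co-registered with lulc")

    def grids(self) -> GridStack:
        return GridStack({name: getattr(self, name) for name in self.GRID_NAMES})

    def predictors(self, names: tuple[str, ...] = DEFAULT_PREDICTORS) -> GridStack:
        """Predictor stack for suitability modelling; slope derived from the DEM."""
        stack = GridStack()
        for name in names:
            if name == "slope":
                stack["slope"] = slope_degrees(self.dem)
            else:
                stack[name] = getattr(self, name)
        return stack

    @property
    def ag_mask(self) -> np.ndarray:
        return self.class_table.mask(self.lulc.values, "is_agriculture")


def gaussian_random_field(
    shape: tuple[int, int], correlation_length: float, seed: int | np.random.Generator
) -> Grid:
    """Smooth zero-mean, unit-variance random field.

    White Gaussian noise is convolved with a Gaussian kernel of width
    ``correlation_length`` (in cells, wrap-around boundary) and then
    re-standardized, so the moments are exact and spatial autocorrelation
    increases with the correlation length.  Deterministic per seed.
    """
    if min(shape) < 1:
        raise ValueError("shape must be positive")
    if correlation_length < 1:
        raise ValueError("correlation_length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=correlation_length, mode="wrap")
    smooth -= smooth.mean()
    sd = smooth.std()
    if sd > 0:
        smooth /= sd
    return Grid(smooth)


def _scaled(field: np.ndarray, mean: float, sd: float, lo: float | None = None,
            hi: float | None = None) -> np.ndarray:
    out = mean + sd * field
    if lo is not None or hi is not None:
        out = np.clip(out, lo, hi)
    return out


def generate_landscape(params: LandscapeParams) -> LandscapeBundle:
    """Generate one landscape bundle; fixed seed gives a bit-identical result."""
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.shape)
    nrows, ncols = shape
    clen = params.correlation_length

    def grf() -> np.ndarray:
        return gaussian_random_field(shape, clen, rng).values

    # --- terrain: tilted rough surface draining toward the bottom edge
    rows = np.arange(nrows, dtype=float)[:, None]
    dem_vals = (
        100.0
        + params.tilt * (nrows - 1 - rows) * np.ones((1, ncols))
        + params.relief * 0.25 * grf()
        + params.relief * 0.05 * rng.standard_normal(shape)
    )

    # --- soils and climate
    ph_vals = _scaled(grf(), 6.4, 0.7, 3.5, 9.0)
    silt_vals = _scaled(grf(), 35.0, 12.0, 1.0, 90.0)
    clay_vals = _scaled(grf(), 25.0, 9.0, 1.0, 80.0)
    som_vals = _scaled(grf(), 3.0, 1.2, 0.1, 12.0)
    precip_vals = _scaled(grf(), 900.0, 150.0, 100.0, None)
    et0_vals = _scaled(grf(), 1100.0, 120.0, 400.0, None)

    geo = dict(cell_size=params.cell_size, origin=(0.0, 0.0))
    dem = Grid(dem_vals, **geo)
    terrain = derive_terrain(dem, stream_threshold=params.stream_threshold)
    slope_vals = terrain.slope.values

    # --- agriculture from the known logistic occurrence model
    predictor_vals = {
        "ph": ph_vals, "slope": slope_vals, "silt": silt_vals,
        "clay": clay_vals, "som": som_vals,
    }
    eta = np.full(shape, params.true_beta[0])
    for b, name in zip(params.true_beta[1:], params.predictor_names):
        vals = predictor_vals[name]
        z = (vals - vals.mean()) / vals.std()
        eta += b * z
    p_ag = 1.0 / (1.0 + np.exp(-eta))
    ag = rng.random(shape) < p_ag

    # --- natural classes by a second latent field, honouring proportions
    lulc = np.zeros(shape, dtype=int)
    lulc[ag] = CLASS_CODES["agriculture"]
    non_ag = ~ag
    n_non_ag = int(non_ag.sum())
    props = params.class_proportions
    natural_names = [n for n in ("forest", "savanna", "grassland") if props.get(n, 0) > 0]
    sprinkle_names = [n for n in ("urban", "water", "barren") if props.get(n, 0) > 0]
    non_ag_total = sum(props.get(n, 0.0) for n in natural_names + sprinkle_names)

    latent = grf()
    order = np.argsort(latent[non_ag], kind="stable")
    flat_idx = np.flatnonzero(non_ag)[order]
    start = 0
    for name in natural_names:
        frac = props[name] / non_ag_total if non_ag_total > 0 else 0.0
        count = int(round(frac * n_non_ag))
        lulc.flat[flat_idx[start:start + count]] = CLASS_CODES[name]
        start += count
    if natural_names:  # remainder from rounding goes to the last natural class
        lulc.flat[flat_idx[start:]] = CLASS_CODES[natural_names[-1]]

    # urban / water / barren sprinkled as scattered cells among non-ag
    for name in sprinkle_names:
        frac = props[name] / non_ag_total if non_ag_total > 0 else 0.0
        count = int(round(frac * n_non_ag))
        free = np.flatnonzero(non_ag.ravel() & np.isin(lulc.ravel(), [CLASS_CODES[n] for n in natural_names]))
        if count > 0 and free.size:
            chosen = rng.choice(free, size=min(count, free.size), replace=False)
            lulc.flat[chosen] = CLASS_CODES[name]

    # --- riparian strips: natural cells within riparian_width of a stream
    if params.riparian_width > 0:
        streams = terrain.stream_mask.values >= 1
        dist = ndimage.distance_transform_edt(~streams)
        near = dist <= params.riparian_width
        natural_cells = np.isin(lulc, [CLASS_CODES[n] for n in natural_names])
        lulc[near & natural_cells] = CLASS_CODES["riparian"]

    # --- yields: increase with a soil-quality index, plus noise
    quality = (
        0.5 * (som_vals - som_vals.mean()) / som_vals.std()
        - 0.3 * np.abs(ph_vals - 6.8) / 0.7
        - 0.2 * (clay_vals - clay_vals.mean()) / clay_vals.std()
    )
    quality = (quality - quality.mean()) / quality.std()
    y_cur = params.base_yield * (1.0 + 0.15 * quality) + 0.3 * rng.standard_normal(shape)
    y_cur = np.maximum(y_cur, 0.5)
    gap = np.clip(params.yield_gap_mean + 0.1 * grf(), 0.05, None)
    y_att = y_cur * (1.0 + gap)

    table = default_class_table()
    return LandscapeBundle(
        lulc=Grid(np.asarray(lulc, dtype=float), **geo),
        dem=dem,
        ph=Grid(ph_vals, **geo),
        silt=Grid(silt_vals, **geo),
        clay=Grid(clay_vals, **geo),
        som=Grid(som_vals, **geo),
        precip=Grid(precip_vals, **geo),
        et0=Grid(et0_vals, **geo),
        yield_current=Grid(y_cur, **geo),
        yield_attainable=Grid(y_att, **geo),
        class_table=table,
        params=params,
        true_probability=Grid(p_ag, **geo),
    )


def write_landscape(bundle: LandscapeBundle, outdir: str | Path, format: str = "geotiff") -> Path:
    """Write all grids, the class-table CSV and a JSON manifest to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = ".tif" if format == "geotiff" else ".asc"
    for name in LandscapeBundle.GRID_NAMES:
        write_grid(getattr(bundle, name), outdir / f"{name}{suffix}", format=format)
    bundle.class_table.to_csv(outdir / "class_table.csv")
    manifest = {"format": format, "grids": list(LandscapeBundle.GRID_NAMES)}
    if bundle.params is not None:
        p = bundle.params
        manifest["params"] = {
            "shape": list(p.shape),
            "cell_size": p.cell_size,
            "correlation_length": p.correlation_length,
            "class_proportions": p.class_proportions,
            "true_beta": list(p.true_beta),
            "predictor_names": list(p.predictor_names),
            "riparian_width": p.riparian_width,
            "stream_threshold": p.stream_threshold,
            "seed": p.seed,
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def read_landscape(indir: str | Path) -> LandscapeBundle:
    """Load a landscape directory written by :func:`write_landscape`."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    fmt = manifest.get("format", "geotiff")
    suffix = ".tif" if fmt == "geotiff" else ".asc"
    grids = {
        name: read_grid(indir / f"{name}{suffix}", format=fmt)
        for name in LandscapeBundle.GRID_NAMES
    }
    table = LulcClassTable.from_csv(indir / "class_table.csv")
    return LandscapeBundle(class_table=table, **grids)
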