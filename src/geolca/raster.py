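"""Single-band raster data model and I/O.

The :class:`Grid` is the universal spatial carrier for every per-pixel
quantity in the pipeline: elevation, soil properties, precipitation and
reference evapotranspiration, yields, suitability probabilities and model
outputs.  Cells are square and uniform; the origin is the upper-left corner
and indices are row-major and 0-based.  A nodata sentinel marks cells that
are excluded from every statistic and model computation.

Two on-disk formats are supported and round-trip bit-exactly:

* ESRI ASCII grid (``.asc``) — plain text, ``NODATA_value`` honoured.
* Single-band TIFF (``.tif``) — written with :mod:`tifffile`; grid metadata
  (cell size, origin, nodata, CRS label) is carried as JSON in the
  ImageDescription tag so that a write/read cycle preserves georeferencing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

__all__ = ["Grid", "GridStack", "read_grid", "write_grid"]

DEFAULT_NODATA = -9999.0


@dataclass
class Grid:
    """A single-band georeferenced raster with a nodata sentinel.

    Parameters
    ----------
    values
        2-D float array, row 0 at the top (north).
    nodata
        Sentinel marking invalid cells.
    cell_size
        Edge length of the (square) cells in metres.
    origin
        ``(x, y)`` of the upper-left corner.
    crs_label
        Free-text coordinate-system label; never interpreted.
    """

    values: np.ndarray
    nodata: float = DEFAULT_NODATA
    cell_size: float = 100.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_label: str = "local"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("Grid values must be a 2-D array of at least 1x1")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of cells that are not nodata (and not NaN)."""
        with np.errstate(invalid="ignore"):
            return (self.values != self.nodata) & ~np.isnan(self.values)

    @property
    def cell_area_ha(self) -> float:
        """Area of one cell in hectares (1 ha = 10,000 m2)."""
        return self.cell_size**2 / 1e4

    def like(self, values: np.ndarray, nodata: float | None = None) -> "Grid":
        """New grid sharing this grid's georeferencing."""
        g = replace(self, values=np.asarray(values, dtype=float))
        if nodata is not None:
            g.nodata = nodata
        return g

    def filled(self, fill: float = np.nan) -> np.ndarray:
        """Values with nodata replaced by ``fill``."""
        out = self.values.copy()
        out[~self.valid] = fill
        return out

    def copy(self) -> "Grid":
        return replace(self, values=self.values.copy())

    def same_georef(self, other: "Grid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= atol
            and abs(self.origin[0] - other.origin[0]) <= atol
            and abs(self.origin[1] - other.origin[1]) <= atol
        )


class GridStack:
    """A named collection of co-registered grids.

    Co-registration (identical shape, cell size and origin) is checked at
    insertion; a violation is an error, never a silent resample.
    """

    def __init__(self, grids: Mapping[str, Grid] | None = None):
        self._grids: dict[str, Grid] = {}
        if grids:
            for name, g in grids.items():
                self[name] = g

    def __setitem__(self, name: str, grid: Grid) -> None:
        if self._grids:
            ref = next(iter(self._grids.values()))
            if not ref.same_georef(grid):
                raise ValueError(
                    f"grid {name!r} is not co-registered with the stack "
                    f"(shape {grid.shape} vs {ref.shape})"
                )
        self._grids[name] = grid

    def __getitem__(self, name: str) -> Grid:
        try:
            return self._grids[name]
        except KeyError:
            raise KeyError(f"missing predictor grid {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._grids

    def __iter__(self) -> Iterator[str]:
        return iter(self._grids)

    def __len__(self) -> int:
        return len(self._grids)

    def names(self) -> list[str]:
        return list(self._grids)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self._grids.values())).shape

    def valid_all(self) -> np.ndarray:
        """Cells valid in every member grid."""
        mask = np.ones(self.shape, dtype=bool)
        for g in self._grids.values():
            mask &= g.valid
        return mask


# ---------------------------------------------------------------------------
# I/O


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".asc", ".agr", ".grd"}:
        return "ascii_grid"
    if suffix in {".tif", ".tiff"}:
        return "geotiff"
    raise ValueError(f"cannot infer raster format from suffix {suffix!r}")


def read_grid(path: str | Path, format: str | None = None) -> Grid:
    """Read a single-band raster.

    ``format`` is ``"geotiff"`` or ``"ascii_grid"``; inferred from the file
    suffix when omitted.  Multi-band rasters and non-square cells are
    rejected.
    """
    path = Path(path)
    fmt = format or _sniff_format(path)
    if fmt == "ascii_grid":
        return _read_ascii(path)
    if fmt == "geotiff":
        return _read_tiff(path)
    raise ValueError(f"unknown raster format {fmt!r}")


def write_grid(grid: Grid, path: str | Path, format: str | None = None) -> Path:
    """Write a grid; the companion of :func:`read_grid` (bit-exact round-trip)."""
    path = Path(path)
    fmt = format or _sniff_format(path)
    if fmt == "ascii_grid":
        _write_ascii(grid, path)
    elif fmt == "geotiff":
        _write_tiff(grid, path)
    else:
        raise ValueError(f"unknown raster format {fmt!r}")
    return path


def _read_ascii(path: Path) -> Grid:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner",
                "cellsize", "dx", "dy", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        values = np.loadtxt(fh, dtype=float, ndmin=2)
    if "dx" in header or "dy" in header:
        if header.get("dx") != header.get("dy"):
            raise ValueError("non-square cells are not supported")
        header["cellsize"] = header["dx"]
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if values.shape != (nrows, ncols):
        raise ValueError(f"{path}: data block is {values.shape}, header says {(nrows, ncols)}")
    cell = header["cellsize"]
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    # header stores the LOWER-left corner; Grid.origin is the upper-left
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    return Grid(values, nodata=nodata, cell_size=cell, origin=origin)


def _write_ascii(grid: Grid, path: Path) -> None:
    nrows, ncols = grid.shape
    x0, y0 = grid.origin
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {float(x0)!r}\n")
        fh.write(f"yllcorner {float(y0 - nrows * grid.cell_size)!r}\n")
        fh.write(f"cellsize {float(grid.cell_size)!r}\n")
        fh.write(f"NODATA_value {float(grid.nodata)!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def _read_tiff(path: Path) -> Grid:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        if len(tf.pages) != 1:
            raise ValueError(f"{path}: multi-band/multi-page rasters are not supported")
        page = tf.pages[0]
        values = page.asarray()
        if values.ndim != 2:
            raise ValueError(f"{path}: multi-band rasters are not supported")
        meta: dict = {}
        if page.description:
            try:
                meta = json.loads(page.description)
            except (ValueError, TypeError):
                meta = {}
    dx = float(meta.get("cell_dx", meta.get("cell_size", 1.0)))
    dy = float(meta.get("cell_dy", dx))
    if dx != dy:
        raise ValueError("non-square cells are not supported")
    return Grid(
        np.asarray(values, dtype=float),
        nodata=float(meta.get("nodata", DEFAULT_NODATA)),
        cell_size=dx,
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        crs_label=str(meta.get("crs_label", "local")),
    )


def _write_tiff(grid: Grid, path: Path) -> None:
    import tifffile

    meta = {
        "cell_size": grid.cell_size,
        "nodata": grid.nodata,
        "origin": list(grid.origin),
        "crs_label": grid.crs_label,
    }
    tifffile.imwrite(path, grid.values.astype(np.float64), description=json.dumps(meta))
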