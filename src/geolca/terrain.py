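"""Terrain derivatives: slope, D8 flow routing, accumulation, streams.

These feed the delivery-ratio models: sediment and nitrogen leaving a cell
are attenuated by the vegetation on the cell's downslope flow path before
reaching a watercourse, so the routing substrate must guarantee that every
valid cell drains to a stream cell or to the grid edge.

Routing is single-direction D8.  Pits are removed by priority-flood filling
with a small epsilon increment, which guarantees a strictly descending
drainage path from every cell to the grid edge (or to a nodata hole, which
is treated as off-grid).  Ties in steepest descent are broken by a fixed
neighbour order: E, SE, S, SW, W, NW, N, NE.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .raster import Grid

__all__ = [
    "TerrainBundle",
    "derive_terrain",
    "downslope_path",
    "fill_pits",
    "path_attenuation",
    "slope_degrees",
]

# D8 neighbour order used for direction codes 0-7 and for tie-breaking.
D8_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1),    # 0 E
    (1, 1),    # 1 SE
    (1, 0),    # 2 S
    (1, -1),   # 3 SW
    (0, -1),   # 4 W
    (-1, -1),  # 5 NW
    (-1, 0),   # 6 N
    (-1, 1),   # 7 NE
)
D8_DIST = tuple(np.hypot(dr, dc) for dr, dc in D8_OFFSETS)
OUTLET = -1  # direction code for cells that drain off the grid


@dataclass
class TerrainBundle:
    """Terrain derivatives sharing the DEM's georeferencing.

    Attributes
    ----------
    slope : Grid
        Slope in degrees (stated in ``slope_units``).
    flow_dir : Grid
        D8 codes 0-7 in the order E, SE, S, SW, W, NW, N, NE; -1 where the
        cell drains off the grid edge (or into a nodata hole).
    flow_acc : Grid
        Number of cells draining through each cell, the cell itself included.
    stream_mask : Grid
        1 where ``flow_acc >= stream_threshold``.
    """

    slope: Grid
    flow_dir: Grid
    flow_acc: Grid
    stream_mask: Grid
    filled_dem: Grid
    stream_threshold: int
    slope_units: str = "degrees"


def slope_degrees(dem: Grid) -> Grid:
    """Central-difference slope magnitude, in degrees."""
    z = dem.filled(np.nan)
    dzdr, dzdc = np.gradient(z, dem.cell_size)
    slope = np.degrees(np.arctan(np.hypot(dzdr, dzdc)))
    slope[~dem.valid] = dem.nodata
    return dem.like(np.nan_to_num(slope, nan=dem.nodata))


def fill_pits(dem: Grid, epsilon: float | None = None) -> Grid:
    """Priority-flood depression filling with an epsilon gradient.

    Filled cells are raised just above their spill elevation so that flats
    left by filling still drain.  Nodata cells act as off-grid sinks.
    """
    valid = dem.valid
    if not valid.any():
        raise ValueError("DEM has no valid cells")
    z = dem.values.copy()
    nrows, ncols = dem.shape
    if epsilon is None:
        span = float(np.ptp(z[valid])) or 1.0
        epsilon = span * 1e-7

    filled = np.full_like(z, np.inf)
    closed = ~valid  # nodata never enters the queue
    heap: list[tuple[float, int, int, int]] = []
    counter = 0

    def is_seed(r: int, c: int) -> bool:
        if r in (0, nrows - 1) or c in (0, ncols - 1):
            return True
        for dr, dc in D8_OFFSETS:
            if not valid[r + dr, c + dc]:
                return True
        return False

    for r in range(nrows):
        for c in range(ncols):
            if valid[r, c] and is_seed(r, c):
                filled[r, c] = z[r, c]
                closed[r, c] = True
                heapq.heappush(heap, (z[r, c], counter, r, c))
                counter += 1

    while heap:
        elev, _, r, c = heapq.heappop(heap)
        for dr, dc in D8_OFFSETS:
            nr, nc = r + dr, c + dc
            if 0 <= nr < nrows and 0 <= nc < ncols and not closed[nr, nc]:
                closed[nr, nc] = True
                filled[nr, nc] = max(z[nr, nc], elev + epsilon)
                heapq.heappush(heap, (filled[nr, nc], counter, nr, nc))
                counter += 1

    filled[~valid] = dem.nodata
    return dem.like(filled)


def _flow_directions(filled: Grid) -> np.ndarray:
    """Steepest-descent D8 codes on the filled DEM (int array; -2 nodata)."""
    z = filled.values
    valid = filled.valid
    nrows, ncols = filled.shape
    fdir = np.full((nrows, ncols), -2, dtype=np.int8)
    for r in range(nrows):
        for c in range(ncols):
            if not valid[r, c]:
                continue
            best_code, best_grade = OUTLET, 0.0
            off_edge = False
            for code, (dr, dc) in enumerate(D8_OFFSETS):
                nr, nc = r + dr, c + dc
                if not (0 <= nr < nrows and 0 <= nc < ncols) or not valid[nr, nc]:
                    off_edge = True
                    continue
                grade = (z[r, c] - z[nr, nc]) / D8_DIST[code]
                if grade > best_grade:  # strict: earlier neighbour wins ties
                    best_code, best_grade = code, grade
            if best_code == OUTLET and not off_edge:
                # epsilon filling guarantees a descending neighbour for
                # interior cells; this is unreachable for a filled DEM
                raise RuntimeError(f"interior cell {(r, c)} has no downslope neighbour")
            fdir[r, c] = best_code
    return fdir


def _flow_accumulation(filled: Grid, fdir: np.ndarray) -> np.ndarray:
    """Upslope cell count (self included), by descending-elevation sweep."""
    z = filled.values
    valid = filled.valid
    acc = np.where(valid, 1.0, 0.0)
    rows, cols = np.nonzero(valid)
    order = np.argsort(-z[rows, cols], kind="stable")
    nrows, ncols = filled.shape
    for i in order:
        r, c = rows[i], cols[i]
        code = fdir[r, c]
        if code >= 0:
            dr, dc = D8_OFFSETS[code]
            acc[r + dr, c + dc] += acc[r, c]
    return acc


def derive_terrain(dem: Grid, stream_threshold: int = 50) -> TerrainBundle:
    """Compute the full terrain bundle from a DEM.

    ``stream_threshold`` is the accumulation count (in cells) above which a
    cell is a stream; every flow path therefore terminates at a stream cell
    or the grid edge.
    """
    valid = dem.valid
    if valid.sum() < 4 or min(dem.shape) < 2:
        raise ValueError("DEM needs at least a 2x2 block of valid cells")
    filled = fill_pits(dem)
    fdir = _flow_directions(filled)
    acc = _flow_accumulation(filled, fdir)
    streams = (acc >= stream_threshold) & valid
    return TerrainBundle(
        slope=slope_degrees(dem),
        flow_dir=dem.like(np.where(valid, fdir, dem.nodata)),
        flow_acc=dem.like(np.where(valid, acc, dem.nodata)),
        stream_mask=dem.like(streams.astype(float)),
        filled_dem=filled,
        stream_threshold=stream_threshold,
    )


def path_attenuation(terrain: TerrainBundle, retention: np.ndarray) -> np.ndarray:
    """Per-cell product of ``(1 - retention)`` along each downslope path.

    ``retention`` gives each cell's interception efficiency in [0, 1].
    The returned factor for cell *i* multiplies material leaving *i* down to
    what reaches the first stream cell (or the grid edge); the path excludes
    *i* itself and the stream cell, matching :func:`downslope_path`.
    Computed bottom-up in a single ascending-elevation sweep, so the cost is
    linear in the number of cells rather than in total path length.
    """
    fdir = terrain.flow_dir.values
    streams = terrain.stream_mask.values >= 1
    valid = terrain.flow_dir.valid
    z = terrain.filled_dem.values
    factor = np.where(valid, 1.0, 0.0)
    rows, cols = np.nonzero(valid)
    order = np.argsort(z[rows, cols], kind="stable")  # downstream first
    for i in order:
        r, c = rows[i], cols[i]
        code = int(fdir[r, c])
        if code < 0 or streams[r, c]:
            continue  # drains off-grid, or is itself a stream: factor 1
        dr, dc = D8_OFFSETS[code]
        nr, nc = r + dr, c + dc
        if streams[nr, nc]:
            continue  # next cell is the stream: empty path, factor 1
        factor[r, c] = (1.0 - retention[nr, nc]) * factor[nr, nc]
    return factor


def downslope_path(terrain: TerrainBundle, pixel: tuple[int, int]) -> list[tuple[int, int]]:
    """Cells between ``pixel`` and its receiving stream cell or the edge.

    The pixel itself and the terminating stream cell are excluded: these are
    exactly the cells whose vegetation can intercept material leaving
    ``pixel`` before it reaches a watercourse.  A stream cell has an empty
    path.  The walk is acyclic by construction (elevation strictly
    decreases along it).
    """
    fdir = terrain.flow_dir.values
    streams = terrain.stream_mask.values
    nrows, ncols = terrain.flow_dir.shape
    r, c = pixel
    if not (0 <= r < nrows and 0 <= c < ncols) or not terrain.flow_dir.valid[r, c]:
        raise ValueError(f"pixel {pixel} is outside the valid grid")
    path: list[tuple[int, int]] = []
    if streams[r, c] >= 1:
        return path
    seen = {(r, c)}
    while True:
        code = int(fdir[r, c])
        if code < 0:
            break
        dr, dc = D8_OFFSETS[code]
        r, c = r + dr, c + dc
        if streams[r, c] >= 1:
            break
        if (r, c) in seen:  # cannot happen on a filled DEM; hard guard
            raise RuntimeError(f"flow cycle at {(r, c)}")
        seen.add((r, c))
        path.append((r, c))
    return path
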