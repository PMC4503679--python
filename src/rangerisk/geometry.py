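"""Range geometry: minimum convex polygons, geodesic areas, habitat
masking, EOO derivation modes and protected-area overlay.

EOO (extent of occurrence) is computed in four nested derivation modes:

``raw_mcp``
    geodesic area of the minimum convex polygon of the records;
``modelled``
    area of the binary suitability range from a distribution model;
``habitat_masked``
    the binary range intersected with suitable habitat (forest AND
    elevation above the montane threshold);
``mcp_clipped``
    the habitat-masked range further clipped to the current MCP — the
    precautionary mode that assumes no migration beyond present range
    boundaries.

Raster areas use cosine-weighted cell areas on the authalic sphere;
polygon areas use a cylindrical equal-area projection of the same
sphere, which preserves spherical areas exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.geometry.polygon import orient
from shapely.ops import transform, unary_union

from .grids import Grid

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088  # authalic radius
KM_PER_DEG = np.pi * EARTH_RADIUS_KM / 180.0  # 111.195...

EOO_MODES = ("raw_mcp", "modelled", "habitat_masked", "mcp_clipped")


class DegenerateHull(ValueError):
    """Fewer than three non-collinear points: no convex polygon exists.

    Species raising this are routed to Data Deficient for EOO-based
    evaluation."""


@dataclass
class MCP:
    """Minimum convex polygon of a species' occurrence points."""

    species_id: str
    vertices: np.ndarray  # (k, 2) lon/lat ring, counter-clockwise, open

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


def convex_hull(points: np.ndarray, species_id: str = "") -> MCP:
    """Minimal convex polygon containing all points.

    Vertices are returned counter-clockwise with collinear boundary
    points removed. Raises DegenerateHull for < 3 points or an
    all-collinear configuration.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) < 3:
        raise DegenerateHull(f"{species_id}: {len(pts)} point(s), need 3 non-collinear")
    hull = shapely.MultiPoint(pts).convex_hull
    if not isinstance(hull, Polygon):
        raise DegenerateHull(f"{species_id}: all points collinear")
    ring = np.asarray(orient(hull, sign=1.0).exterior.coords)[:-1]
    return MCP(species_id, ring)


@dataclass
class RangeEstimate:
    species_id: str
    mode: str
    epoch: str
    area_km2: float

    def __post_init__(self) -> None:
        if self.mode not in EOO_MODES:
            raise ValueError(f"unknown EOO mode {self.mode!r}")
        if self.area_km2 < 0:
            raise ValueError("area_km2 must be >= 0")


def cell_areas_km2(grid: Grid) -> np.ndarray:
    """Per-cell areas, cosine-weighted by cell-centre latitude."""
    lat = np.deg2rad(grid.lat_centers)
    row_area = (KM_PER_DEG * grid.cell_size_deg) ** 2 * np.cos(lat)
    return np.repeat(row_area[:, None], grid.n_cols, axis=1)


def raster_area_km2(mask: np.ndarray, grid: Grid) -> float:
    """Area of the True cells of ``mask`` on the grid."""
    mask = np.asarray(mask)
    if mask.shape != grid.data.shape:
        raise ValueError("mask shape does not match grid")
    return float(cell_areas_km2(grid)[mask.astype(bool)].sum())


def _equal_area(lon, lat):
    """Cylindrical equal-area projection of the authalic sphere (km)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    return EARTH_RADIUS_KM * np.deg2rad(lon), EARTH_RADIUS_KM * np.sin(np.deg2rad(lat))


def polygon_area_km2(geom) -> float:
    """Geodesic area of a lon/lat polygon (or MCP), in km^2."""
    if isinstance(geom, MCP):
        geom = geom.polygon
    if geom.is_empty:
        return 0.0
    return float(transform(_equal_area, geom).area)


def geodesic_area(obj, grid: Grid | None = None) -> float:
    """Area in km^2 of a boolean cell mask (needs ``grid``), a shapely
    polygon, or an MCP. Empty geometry gives 0."""
    if isinstance(obj, (MCP,)) or hasattr(obj, "is_empty"):
        return polygon_area_km2(obj)
    if grid is None:
        raise ValueError("raster areas need the grid georeference")
    return raster_area_km2(obj, grid)


def _aggregate_majority(data: np.ndarray, factor: int) -> np.ndarray:
    r, c = data.shape
    if r % factor or c % factor:
        raise ValueError("finer raster extent is not a multiple of the target lattice")
    blocks = data.reshape(r // factor, factor, c // factor, factor)
    frac = blocks.mean(axis=(1, 3))
    return frac >= 0.5


def habitat_mask(forest: Grid, terrain: Grid, threshold_m: float = 1500.0) -> np.ndarray:
    """Suitable-habitat cells: forest AND elevation >= threshold.

    A forest raster at an integer multiple finer resolution is
    aggregated to the terrain lattice by majority rule (a cell is forest
    iff at least half of its sub-cells are).
    """
    if terrain.same_georef(forest):
        forest_cells = forest.data > 0
    else:
        ratio = terrain.cell_size_deg / forest.cell_size_deg
        if not (np.isclose(ratio, round(ratio)) and round(ratio) >= 2):
            raise ValueError("forest raster is not co-registered with the terrain")
        if not np.allclose(forest.origin, terrain.origin):
            raise ValueError("forest raster origin does not match terrain")
        forest_cells = _aggregate_majority(forest.data > 0, int(round(ratio)))
        if forest_cells.shape != terrain.data.shape:
            raise ValueError("aggregated forest raster does not match terrain shape")
    return forest_cells & (terrain.data >= threshold_m)


def rasterize(geom, grid: Grid) -> np.ndarray:
    """Boolean cell mask of a polygon (or MCP, or polygon list) by
    cell-centre inclusion; centres on the boundary count as inside."""
    if isinstance(geom, MCP):
        geom = geom.polygon
    if isinstance(geom, (list, tuple)):
        if not geom:
            return np.zeros(grid.data.shape, dtype=bool)
        geom = unary_union(list(geom))
    lon, lat = grid.center_mesh()
    return shapely.intersects_xy(geom, lon.ravel(), lat.ravel()).reshape(grid.data.shape)


def eoo(
    mode: str,
    *,
    species_id: str = "",
    epoch: str = "current",
    records: np.ndarray | None = None,
    binary_map: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    mcp: MCP | None = None,
    grid: Grid | None = None,
) -> RangeEstimate:
    """Extent of occurrence under one derivation mode.

    raw_mcp needs ``records``; modelled needs ``binary_map`` + ``grid``;
    habitat_masked additionally ``mask``; mcp_clipped additionally
    ``mcp``. DegenerateHull propagates to the caller, which should route
    the species to DD.
    """
    if mode == "raw_mcp":
        if records is None:
            raise ValueError("raw_mcp mode needs records")
        hull = convex_hull(records, species_id)
        return RangeEstimate(species_id, mode, epoch, polygon_area_km2(hull))
    if binary_map is None or grid is None:
        raise ValueError(f"{mode} mode needs binary_map and grid")
    cells = np.asarray(binary_map, dtype=bool)
    if mode in ("habitat_masked", "mcp_clipped"):
        if mask is None:
            raise ValueError(f"{mode} mode needs a habitat mask")
        cells = cells & np.asarray(mask, dtype=bool)
    if mode == "mcp_clipped":
        if mcp is None:
            raise ValueError("mcp_clipped mode needs the current MCP")
        cells = cells & rasterize(mcp, grid)
    elif mode not in ("modelled", "habitat_masked"):
        raise ValueError(f"unknown EOO mode {mode!r}")
    return RangeEstimate(species_id, mode, epoch, raster_area_km2(cells, grid))


def range_change(current: RangeEstimate, future: RangeEstimate) -> float | None:
    """Proportional EOO decline (negative = expansion).

    Returns None when the current area is zero (undefined decline; the
    species should be treated as Data Deficient under criterion A3).
    """
    if current.species_id != future.species_id:
        raise ValueError("range_change compares one species with itself")
    if current.mode != future.mode:
        raise ValueError(f"mode mismatch: {current.mode} vs {future.mode}")
    if current.area_km2 == 0:
        log.warning("%s: current EOO is 0 km^2; decline undefined -> DD", current.species_id)
        return None
    return (current.area_km2 - future.area_km2) / current.area_km2


def protected_coverage(
    range_obj, protected: Sequence, grid: Grid | None = None
) -> float | None:
    """Percentage of a range located inside the protected-area network.

    ``range_obj`` is a boolean cell mask (with ``grid``) or an
    MCP/polygon, rasterized to the analysis lattice by cell-centre
    inclusion. Empty ranges give None (undefined, logged).
    """
    if isinstance(range_obj, np.ndarray):
        if grid is None:
            raise ValueError("raster ranges need the grid")
        cells = range_obj.astype(bool)
    else:
        if grid is None:
            raise ValueError("polygon ranges need the grid for the overlay lattice")
        cells = rasterize(range_obj, grid)
    total = raster_area_km2(cells, grid)
    if total == 0:
        log.warning("empty range: protected coverage undefined")
        return None
    inside = cells & rasterize(list(protected), grid)
    return 100.0 * raster_area_km2(inside, grid) / total
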