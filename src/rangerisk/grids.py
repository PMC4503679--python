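"""Raster containers on a regular longitude/latitude lattice.

All grids in the package share one convention: ``data[0, 0]`` is the
north-west cell, rows run north to south, columns west to east, and
``origin`` is the (lon, lat) of the grid's outer north-west corner.
Cell membership for a point uses half-open intervals
[west, east) x (south, north], so a point on a shared edge belongs to
exactly one cell.

Rasters are exchanged on disk as single-band ESRI ASCII grids (.asc),
a plain-text format understood by GDAL, QGIS and ArcGIS.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

NODATA = -9999.0

#: The four bioclimatic predictor layers used throughout the package:
#: mean annual temperature, mean diurnal range, precipitation of the
#: wettest month and precipitation of the driest month.
CLIMATE_VARIABLES = (
    "mean_annual_temp_C",
    "diurnal_range_C",
    "precip_wettest_mm",
    "precip_driest_mm",
)


class GeoreferenceError(ValueError):
    """Raised when two grids that must be co-registered are not."""


@dataclass
class Grid:
    """A single-band raster on a regular lon/lat lattice."""

    data: np.ndarray
    origin: tuple[float, float]  # (lon, lat) of the NW corner
    cell_size_deg: float
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("grid data must be 2-D")
        if self.cell_size_deg <= 0:
            raise ValueError("cell_size_deg must be positive")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    @property
    def west(self) -> float:
        return self.origin[0]

    @property
    def north(self) -> float:
        return self.origin[1]

    @property
    def east(self) -> float:
        return self.west + self.n_cols * self.cell_size_deg

    @property
    def south(self) -> float:
        return self.north - self.n_rows * self.cell_size_deg

    @property
    def lon_centers(self) -> np.ndarray:
        return self.west + (np.arange(self.n_cols) + 0.5) * self.cell_size_deg

    @property
    def lat_centers(self) -> np.ndarray:
        return self.north - (np.arange(self.n_rows) + 0.5) * self.cell_size_deg

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of cell centres, each shaped like ``data``."""
        lon, lat = np.meshgrid(self.lon_centers, self.lat_centers)
        return lon, lat

    def georef(self) -> tuple[tuple[float, float], float, tuple[int, int]]:
        return (self.origin, self.cell_size_deg, self.data.shape)

    def same_georef(self, other: "Grid") -> bool:
        a, b = self.georef(), other.georef()
        return (
            np.allclose(a[0], b[0])
            and np.isclose(a[1], b[1])
            and a[2] == b[2]
        )

    def require_georef(self, other: "Grid") -> None:
        if not self.same_georef(other):
            raise GeoreferenceError(
                f"grids are not co-registered: {self.georef()} vs {other.georef()}"
            )

    def cell_index(self, lon, lat) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map points to (row, col) with half-open cell intervals.

        Returns (row, col, inside) arrays; row/col are only meaningful
        where ``inside`` is True.
        """
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        col = np.floor((lon - self.west) / self.cell_size_deg).astype(int)
        # lat in (south_edge, north_edge] -> use ceil on the offset from north
        off = (self.north - lat) / self.cell_size_deg
        row = np.ceil(off).astype(int) - 1
        row[np.isclose(lat, self.north)] = 0  # the outer north edge belongs to row 0
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        inside &= lon < self.east  # east outer edge excluded by [west, east)
        return row, col, inside

    def sample(self, lon, lat) -> np.ndarray:
        """Cell values at points; NaN for out-of-extent points."""
        row, col, inside = self.cell_index(lon, lat)
        out = np.full(row.shape, np.nan)
        out[inside] = self.data[row[inside], col[inside]]
        return out

    def write_ascii(self, path: str | Path, fmt: str = "%.6g") -> None:
        path = Path(path)
        data = np.where(np.isfinite(self.data), self.data, self.nodata)
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.west:.10g}\n"
            f"yllcorner {self.south:.10g}\n"
            f"cellsize {self.cell_size_deg:.10g}\n"
            f"NODATA_value {self.nodata:.10g}\n"
        )
        with path.open("w") as fh:
            fh.write(header)
            np.savetxt(fh, data, fmt=fmt)

    @classmethod
    def read_ascii(cls, path: str | Path) -> "Grid":
        path = Path(path)
        meta: dict[str, float] = {}
        with path.open() as fh:
            for _ in range(6):
                key, value = fh.readline().split()
                meta[key.lower()] = float(value)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        nodata = meta.get("nodata_value", NODATA)
        data = np.where(data == nodata, np.nan, data)
        cell = meta["cellsize"]
        origin = (meta["xllcorner"], meta["yllcorner"] + meta["nrows"] * cell)
        return cls(data=data, origin=origin, cell_size_deg=cell, nodata=nodata)


@dataclass
class ClimateStack:
    """Co-registered climate layers for one epoch or scenario.

    ``layers`` maps variable name to a 2-D array; all layers share the
    georeference given by ``origin`` and ``cell_size_deg``.
    """

    layers: dict[str, np.ndarray]
    origin: tuple[float, float]
    cell_size_deg: float
    epoch: str = "current"

    def __post_init__(self) -> None:
        shapes = {name: np.asarray(a).shape for name, a in self.layers.items()}
        if len(set(shapes.values())) > 1:
            raise GeoreferenceError(f"mismatched layer shapes: {shapes}")
        self.layers = {n: np.asarray(a, dtype=float) for n, a in self.layers.items()}

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.layers)

    def grid(self, name: str) -> Grid:
        return Grid(self.layers[name], self.origin, self.cell_size_deg)

    def template(self) -> Grid:
        """An empty Grid carrying this stack's georeference."""
        return Grid(np.zeros(self.shape), self.origin, self.cell_size_deg)

    def __iter__(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(self.layers.items())

    def copy(self) -> "ClimateStack":
        return ClimateStack(
            {n: a.copy() for n, a in self.layers.items()},
            self.origin,
            self.cell_size_deg,
            self.epoch,
        )

    def with_epoch(self, epoch: str) -> "ClimateStack":
        out = self.copy()
        out.epoch = epoch
        return out

    def require_georef(self, other: "Grid | ClimateStack") -> None:
        mine = self.template()
        theirs = other if isinstance(other, Grid) else other.template()
        mine.require_georef(theirs)

    def covariates_at(self, lon, lat, variables: tuple[str, ...] | None = None) -> np.ndarray:
        """(n, k) covariate matrix at point locations (NaN outside extent)."""
        variables = variables or self.names
        cols = [self.grid(v).sample(lon, lat) for v in variables]
        return np.column_stack(cols)

    def write_ascii(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, _ in self:
            self.grid(name).write_ascii(directory / f"{name}.asc")

    @classmethod
    def read_ascii(cls, directory: str | Path, epoch: str = "current") -> "ClimateStack":
        directory = Path(directory)
        grids = {p.stem: Grid.read_ascii(p) for p in sorted(directory.glob("*.asc"))}
        if not grids:
            raise FileNotFoundError(f"no .asc layers in {directory}")
        first = next(iter(grids.values()))
        for g in grids.values():
            first.require_georef(g)
        return cls(
            {n: g.data for n, g in grids.items()},
            first.origin,
            first.cell_size_deg,
            epoch,
        )
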