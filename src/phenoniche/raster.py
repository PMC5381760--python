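"""Lightweight raster grids and ESRI ASCII grid I/O.

Rasters are plain 2D numpy arrays (row 0 = northernmost row) tied to a
:class:`GridSpec`; nodata cells are ``NaN``.  An :class:`EnvStack` is a set of
named, grid-aligned layers sharing one validity mask.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = ["GridSpec", "Raster", "EnvStack", "read_ascii_grid", "write_ascii_grid"]

_NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat grid (cell-registered, row 0 on top)."""

    nrows: int
    ncols: int
    xll: float
    yll: float
    cellsize: float

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.xll,
            self.yll,
            self.xll + self.ncols * self.cellsize,
            self.yll + self.nrows * self.cellsize,
        )

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.xll + (col + 0.5) * self.cellsize
        lat = self.yll + (self.nrows - row - 0.5) * self.cellsize
        return lon, lat

    def index_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cells containing the points; -1 where off-grid."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        col = np.floor((lon - self.xll) / self.cellsize).astype(int)
        row = self.nrows - 1 - np.floor((lat - self.yll) / self.cellsize).astype(int)
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        return row, col


@dataclass
class Raster:
    """Single-band raster; nodata represented as NaN."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True on valid (non-nodata) cells."""
        return np.isfinite(self.values)

    def sample(self, lon, lat) -> np.ndarray:
        """Value at each point; NaN off-grid or on nodata."""
        row, col = self.grid.index_of(lon, lat)
        out = np.full(row.shape, np.nan)
        ok = row >= 0
        out[ok] = self.values[row[ok], col[ok]]
        return out


class EnvStack:
    """Named, grid-aligned continuous layers with a shared nodata mask."""

    def __init__(self, grid: GridSpec, layers: Mapping[str, np.ndarray]):
        if not layers:
            raise ValueError("EnvStack needs at least one layer")
        self.grid = grid
        self.layers: dict[str, np.ndarray] = {}
        for name, arr in layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != grid.shape:
                raise ValueError(f"layer {name!r} shape {arr.shape} != grid {grid.shape}")
            if name in self.layers:
                raise ValueError(f"duplicate layer name {name!r}")
            self.layers[name] = arr
        stack = np.stack(list(self.layers.values()))
        self.mask = np.all(np.isfinite(stack), axis=0)

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __getitem__(self, name: str) -> Raster:
        return Raster(self.grid, self.layers[name])

    def subset(self, names: Iterable[str]) -> "EnvStack":
        names = list(names)
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return EnvStack(self.grid, {n: self.layers[n] for n in names})

    def sample(self, lon, lat) -> dict[str, np.ndarray]:
        """Per-layer values at the points (NaN off-grid/nodata)."""
        return {name: self[name].sample(lon, lat) for name in self.layers}

    def table(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(n_points, n_layers) matrix of layer values at cell indices."""
        return np.column_stack([self.layers[n][rows, cols] for n in self.layers])

    def valid_indices(self) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.mask)

    def write(self, directory: str | Path, fmt: str = "asc") -> list[Path]:
        """Write every layer as an ESRI ASCII grid ``<name>.asc``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, arr in self.layers.items():
            p = directory / f"{name}.asc"
            write_ascii_grid(p, Raster(self.grid, arr))
            paths.append(p)
        return paths

    @classmethod
    def from_rasters(cls, rasters: Mapping[str, Raster]) -> "EnvStack":
        grids = {r.grid for r in rasters.values()}
        if len(grids) != 1:
            raise ValueError("all rasters must share a grid")
        return cls(grids.pop(), {n: r.values for n, r in rasters.items()})


def write_ascii_grid(path: str | Path, raster: Raster, nodata: float = _NODATA) -> Path:
    path = Path(path)
    g = raster.grid
    vals = np.where(np.isfinite(raster.values), raster.values, nodata)
    buf = io.StringIO()
    buf.write(f"ncols {g.ncols}\n")
    buf.write(f"nrows {g.nrows}\n")
    buf.write(f"xllcorner {g.xll!r}\n")
    buf.write(f"yllcorner {g.yll!r}\n")
    buf.write(f"cellsize {g.cellsize!r}\n")
    buf.write(f"NODATA_value {nodata!r}\n")
    np.savetxt(buf, vals, fmt="%.10g")
    path.write_text(buf.getvalue())
    return path


def read_ascii_grid(path: str | Path) -> Raster:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines[:6]:
        parts = line.split()
        if len(parts) == 2 and parts[0][0].isalpha():
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:  # pragma: no cover - defensive
            break
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required <= set(header):
        raise ValueError(f"{path}: missing ASCII grid header keys {required - set(header)}")
    values = np.loadtxt(io.StringIO("".join(lines[n_header:])))
    values = np.atleast_2d(values)
    nodata = header.get("nodata_value", _NODATA)
    values = np.where(values == nodata, np.nan, values)
    grid = GridSpec(
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
    )
    return Raster(grid, values)
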