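"""Gridded environmental layers and suitability rasters.

A :class:`ClimateStack` holds named 2-D environmental grids (e.g. the 19
WorldClim bioclimatic predictors) that share shape, geographic transform
and nodata mask.  Grids follow raster convention: row 0 is the northernmost
row; the transform is the ESRI ASCII grid header triple (xllcorner,
yllcorner, cellsize) in the layers' native coordinates (WGS84 lat-long in
the study setting — no great-circle corrections are applied).

I/O is the ESRI ASCII grid (.asc) format, one file per variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridTransform:
    """Lower-left corner and square cell size of a north-up grid."""

    xllcorner: float
    yllcorner: float
    cellsize: float

    def cell_of(self, lon: float, lat: float, nrows: int) -> tuple[int, int]:
        """(row, col) of a geographic point; row 0 is the top row."""
        col = int(np.floor((lon - self.xllcorner) / self.cellsize))
        row_from_bottom = int(np.floor((lat - self.yllcorner) / self.cellsize))
        return nrows - 1 - row_from_bottom, col

    def center_of(self, row: int, col: int, nrows: int) -> tuple[float, float]:
        lon = self.xllcorner + (col + 0.5) * self.cellsize
        lat = self.yllcorner + (nrows - 1 - row + 0.5) * self.cellsize
        return lon, lat


@dataclass
class ClimateStack:
    """Aligned environmental rasters with a shared grid and validity mask."""

    names: list[str]
    grids: np.ndarray  # (n_vars, nrows, ncols) float
    transform: GridTransform
    mask: np.ndarray  # (nrows, ncols) bool, True = valid cell

    def __post_init__(self) -> None:
        self.grids = np.asarray(self.grids, dtype=float)
        if self.grids.ndim != 3 or self.grids.shape[0] != len(self.names):
            raise ValueError("grids must be (n_vars, nrows, ncols) matching names")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grids.shape[1:]:
            raise ValueError("mask shape does not match grids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grids.shape[1:]

    @property
    def nrows(self) -> int:
        return self.grids.shape[1]

    @property
    def ncols(self) -> int:
        return self.grids.shape[2]

    @property
    def n_vars(self) -> int:
        return len(self.names)

    def grid(self, name: str) -> np.ndarray:
        return self.grids[self.names.index(name)]

    def valid_cells(self) -> np.ndarray:
        """(n_valid, 2) array of (row, col) indices of valid cells."""
        return np.argwhere(self.mask)

    def cell_of_points(self, points: np.ndarray) -> np.ndarray:
        """(n, 2) rows/cols for an (n, 2) array of (lon, lat) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        cols = np.floor((pts[:, 0] - self.transform.xllcorner) / self.transform.cellsize)
        rfb = np.floor((pts[:, 1] - self.transform.yllcorner) / self.transform.cellsize)
        rows = self.nrows - 1 - rfb
        return np.stack([rows, cols], axis=1).astype(int)

    def in_bounds(self, cells: np.ndarray) -> np.ndarray:
        r, c = cells[:, 0], cells[:, 1]
        return (r >= 0) & (r < self.nrows) & (c >= 0) & (c < self.ncols)

    def extract(self, points: np.ndarray) -> np.ndarray:
        """Environmental values (n, n_vars) at points; NaN off-grid/nodata."""
        cells = self.cell_of_points(points)
        ok = self.in_bounds(cells)
        out = np.full((len(cells), self.n_vars), np.nan)
        r, c = cells[ok, 0], cells[ok, 1]
        valid = self.mask[r, c]
        vals = self.grids[:, r, c].T
        vals[~valid] = np.nan
        out[ok] = vals
        return out

    def values_at_cells(self, cells: np.ndarray) -> np.ndarray:
        return self.grids[:, cells[:, 0], cells[:, 1]].T

    def env_table(self) -> np.ndarray:
        """(n_valid_cells, n_vars) environment matrix over valid cells."""
        cells = self.valid_cells()
        return self.values_at_cells(cells)

    def subset(self, names: Sequence[str]) -> "ClimateStack":
        idx = [self.names.index(n) for n in names]
        return ClimateStack(list(names), self.grids[idx], self.transform, self.mask)


@dataclass
class SuitabilityRaster:
    """Continuous suitability surface on a stack's grid.

    ``scale`` records the value convention: ``raw`` (normalised to sum 1
    over the background reference), ``cloglog`` or ``rescaled01`` (both in
    [0, 1]).  Invalid cells are NaN.
    """

    values: np.ndarray
    scale: str
    mask: np.ndarray
    transform: Optional[GridTransform] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values/mask shape mismatch")
        if self.scale in ("cloglog", "rescaled01"):
            v = self.values[self.mask]
            if v.size and ((v < -1e-9).any() or (v > 1 + 1e-9).any()):
                raise ValueError(f"{self.scale} values must lie in [0, 1]")

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def at_points(self, points: np.ndarray, stack: ClimateStack) -> np.ndarray:
        cells = stack.cell_of_points(points)
        ok = stack.in_bounds(cells)
        out = np.full(len(cells), np.nan)
        out[ok] = self.values[cells[ok, 0], cells[ok, 1]]
        return out


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def read_ascii_grid(path) -> tuple[np.ndarray, GridTransform, float]:
    """Read one ESRI ASCII grid; returns (values, transform, nodata)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: missing header field {req}")
    nodata = header.get("nodata_value", -9999.0)
    values = np.loadtxt(lines[i:], dtype=float)
    values = np.atleast_2d(values)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: data shape {values.shape} disagrees with header")
    tr = GridTransform(header["xllcorner"], header["yllcorner"], header["cellsize"])
    return values, tr, nodata


def write_ascii_grid(
    values: np.ndarray,
    transform: GridTransform,
    path,
    nodata: float = -9999.0,
    mask: Optional[np.ndarray] = None,
) -> None:
    vals = np.asarray(values, dtype=float).copy()
    if mask is not None:
        vals[~np.asarray(mask, dtype=bool)] = nodata
    vals[np.isnan(vals)] = nodata
    nrows, ncols = vals.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {transform.xllcorner:.10g}\n")
        fh.write(f"yllcorner {transform.yllcorner:.10g}\n")
        fh.write(f"cellsize {transform.cellsize:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_stack(directory, names: Optional[Sequence[str]] = None) -> ClimateStack:
    """Read a directory of per-variable .asc grids into a stack.

    Variables are named after file stems; all grids must agree on shape and
    transform.  The shared mask is the intersection of per-grid validity.
    """
    directory = Path(directory)
    paths = (
        [directory / f"{n}.asc" for n in names]
        if names is not None
        else sorted(directory.glob("*.asc"))
    )
    if not paths:
        raise FileNotFoundError(f"no .asc grids in {directory}")
    grids, tr0 = [], None
    mask = None
    out_names = []
    for p in paths:
        vals, tr, nodata = read_ascii_grid(p)
        if tr0 is None:
            tr0 = tr
        elif tr != tr0 or (grids and vals.shape != grids[0].shape):
            raise ValueError(f"{p}: grid/transform disagrees with first layer")
        valid = vals != nodata
        vals = np.where(valid, vals, np.nan)
        mask = valid if mask is None else (mask & valid)
        grids.append(vals)
        out_names.append(p.stem)
    return ClimateStack(out_names, np.stack(grids), tr0, mask)


def write_stack(stack: ClimateStack, directory, nodata: float = -9999.0) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, grid in zip(stack.names, stack.grids):
        write_ascii_grid(grid, stack.transform, directory / f"{name}.asc",
                         nodata=nodata, mask=stack.mask)
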