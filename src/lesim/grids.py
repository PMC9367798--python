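"""Raster data model and shared grid operations.

Every stage of the pipeline works on co-registered rectangular grids:
categorical land-use maps, continuous driver surfaces, distance rasters,
suitability images. This module provides the common container
(:class:`RasterGrid`), text and TIFF I/O, alignment checks, Euclidean
distance transforms, and min-max rescaling.

Conventions
-----------
* Coordinates are 0-based ``(row, col)`` with row 0 at the top of the map.
* ``cell_size`` is in meters; the default 30 m cell covers 900 m**2, and
  area figures are reported in km**2 (``cells * cell_size**2 / 1e6``).
* ``origin`` is the (x, y) map coordinate of the lower-left corner, as in
  the ESRI ASCII grid header.
* nodata cells are excluded from every statistic, transition count, and
  allocation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "RasterGrid",
    "LandUseMap",
    "DEFAULT_LEGEND",
    "read_raster",
    "write_raster",
    "check_aligned",
    "euclidean_distance",
    "minmax_rescale",
]

#: Default six-class legend shared by the whole pipeline.
DEFAULT_LEGEND: dict[int, str] = {
    1: "farmland",
    2: "woodland",
    3: "grassland",
    4: "water",
    5: "construction",
    6: "unused",
}


@dataclass
class RasterGrid:
    """A rectangular raster with square cells.

    Parameters
    ----------
    values
        2-D array of cell values. Integer dtype for categorical grids,
        float for continuous ones.
    cell_size
        Side length of a cell in meters (> 0).
    origin
        (x, y) map coordinate of the lower-left corner.
    nodata
        Sentinel value marking cells outside the study area.
    """

    values: np.ndarray
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("values must be a non-empty 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        data = self.values[self.mask]
        if data.size and not np.all(np.isfinite(data.astype(float))):
            raise ValueError("non-nodata values must be finite")

    # -- basic geometry -------------------------------------------------

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell carries data."""
        vals = self.values
        with np.errstate(invalid="ignore"):
            m = vals != self.nodata
        if np.issubdtype(vals.dtype, np.floating):
            m &= np.isfinite(vals)
        return m

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size**2 / 1e6

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.cell_size, other.cell_size)
            and math.isclose(self.origin[0], other.origin[0])
            and math.isclose(self.origin[1], other.origin[1])
        )

    def with_values(self, values: np.ndarray) -> "RasterGrid":
        """New grid sharing this grid's georeferencing."""
        return replace(self, values=np.asarray(values))


@dataclass
class LandUseMap:
    """A categorical raster with a class legend.

    The legend maps integer codes to at most six class names drawn from
    the standard set (farmland, woodland, grassland, water, construction,
    unused). Every non-nodata cell code must appear in the legend.
    """

    grid: RasterGrid
    legend: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))

    def __post_init__(self) -> None:
        if not np.issubdtype(self.grid.values.dtype, np.integer):
            raise ValueError("land-use grid must hold integer codes")
        if len(self.legend) > 6:
            raise ValueError("legend has more than 6 classes")
        present = np.unique(self.grid.values[self.grid.mask])
        unknown = set(present.tolist()) - set(self.legend)
        if unknown:
            raise ValueError(f"codes {sorted(unknown)} missing from legend")

    @property
    def codes(self) -> list[int]:
        return sorted(self.legend)

    def class_mask(self, code: int) -> np.ndarray:
        return (self.grid.values == code) & self.grid.mask

    def class_counts(self) -> dict[int, int]:
        """Cells per legend code (nodata excluded)."""
        vals = self.grid.values[self.grid.mask]
        return {c: int(np.sum(vals == c)) for c in self.codes}

    def class_areas_km2(self) -> dict[int, float]:
        a = self.grid.cell_area_km2
        return {c: n * a for c, n in self.class_counts().items()}


# ---------------------------------------------------------------------------
# I/O: ESRI ASCII grid and TIFF (values + JSON sidecar for georeferencing)
# ---------------------------------------------------------------------------

_ASCII_SUFFIXES = {".asc", ".txt", ".grd"}
_TIFF_SUFFIXES = {".tif", ".tiff"}


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".aux.json")


def read_raster(path: str | Path, kind: str = "continuous") -> RasterGrid:
    """Read an ESRI ASCII grid or TIFF raster.

    ``kind='categorical'`` enforces integer codes and returns an integer
    array; non-integral values raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        import tifffile

        values = np.asarray(tifffile.imread(path))
        meta = {"cell_size": 30.0, "origin": [0.0, 0.0], "nodata": -9999.0}
        sc = _sidecar(path)
        if sc.exists():
            meta.update(json.loads(sc.read_text()))
        grid = RasterGrid(
            values,
            cell_size=float(meta["cell_size"]),
            origin=tuple(meta["origin"]),
            nodata=float(meta["nodata"]),
        )
    else:
        grid = _read_ascii(path)
    if kind == "categorical":
        vals = grid.values
        if not np.issubdtype(vals.dtype, np.integer):
            rounded = np.rint(vals)
            if not np.allclose(vals[grid.mask], rounded[grid.mask], atol=1e-9):
                raise ValueError(f"{path}: non-integer values in categorical mode")
            grid = grid.with_values(rounded.astype(np.int32))
            grid.nodata = float(int(grid.nodata)) if float(grid.nodata).is_integer() else grid.nodata
    elif kind != "continuous":
        raise ValueError("kind must be 'categorical' or 'continuous'")
    return grid


def _read_ascii(path: Path) -> RasterGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner",
                "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        body = np.loadtxt(fh, ndmin=2)
    if "ncols" not in header or "nrows" not in header:
        raise ValueError(f"{path}: not an ESRI ASCII grid (missing header)")
    if body.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: body shape {body.shape} disagrees with header")
    if np.allclose(body, np.rint(body)):
        body = np.rint(body).astype(np.int32)
    return RasterGrid(
        body,
        cell_size=header.get("cellsize", 30.0),
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        nodata=header.get("nodata_value", -9999.0),
    )


def write_raster(grid: RasterGrid, path: str | Path) -> Path:
    """Write a grid as ESRI ASCII (.asc/.txt) or TIFF (.tif, with sidecar)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffix = path.suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        import tifffile

        tifffile.imwrite(path, grid.values)
        _sidecar(path).write_text(
            json.dumps(
                {
                    "cell_size": grid.cell_size,
                    "origin": list(grid.origin),
                    "nodata": grid.nodata,
                }
            )
        )
        return path
    if suffix not in _ASCII_SUFFIXES:
        raise ValueError(f"unsupported raster format: {suffix}")
    integral = np.issubdtype(grid.values.dtype, np.integer)
    nodata = int(grid.nodata) if integral and float(grid.nodata).is_integer() else grid.nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.cols}\n")
        fh.write(f"nrows {grid.rows}\n")
        fh.write(f"xllcorner {grid.origin[0]}\n")
        fh.write(f"yllcorner {grid.origin[1]}\n")
        fh.write(f"cellsize {grid.cell_size}\n")
        fh.write(f"NODATA_value {nodata}\n")
        fmt = "%d" if integral else "%.10g"
        np.savetxt(fh, grid.values, fmt=fmt)
    return path


# ---------------------------------------------------------------------------
# Grid operations
# ---------------------------------------------------------------------------


def check_aligned(grids: list[RasterGrid]) -> bool:
    """True iff all grids share shape, cell size, and origin."""
    if not grids:
        raise ValueError("empty grid list")
    first = grids[0]
    return all(first.aligned_with(g) for g in grids[1:])


def euclidean_distance(targets: RasterGrid) -> RasterGrid:
    """Distance (m) from every cell center to the nearest target cell.

    ``targets`` is a boolean (or 0/1) grid; target cells get distance 0.
    Exact Euclidean distance transform, center-to-center, in map units.
    """
    t = targets.values.astype(bool)
    if not t.any():
        raise ValueError("no target cells")
    dist = ndimage.distance_transform_edt(~t, sampling=targets.cell_size)
    return targets.with_values(dist.astype(float))


def minmax_rescale(grid: RasterGrid, direction: str = "increasing") -> RasterGrid:
    """Linearly rescale non-nodata values to [0, 1].

    ``increasing`` maps min -> 0, max -> 1; ``decreasing`` maps min -> 1,
    max -> 0. nodata cells are preserved. A constant grid is an error.
    """
    if direction not in {"increasing", "decreasing"}:
        raise ValueError("direction must be 'increasing' or 'decreasing'")
    m = grid.mask
    data = grid.values[m].astype(float)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        raise ValueError("cannot rescale a constant grid")
    out = np.full(grid.shape, grid.nodata, dtype=float)
    scaled = (grid.values[m].astype(float) - lo) / (hi - lo)
    out[m] = scaled if direction == "increasing" else 1.0 - scaled
    res = grid.with_values(out)
    res.nodata = float(grid.nodata)
    return res
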