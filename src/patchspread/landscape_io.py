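"""Raster and point-table I/O plus the scalar grid transforms.

Rasters are held as numpy arrays on a regular projected grid with
cell-centre registration; row 0 is the northernmost row.  The on-disk
dialect is the single-band ESRI ASCII grid (``ncols/nrows/xllcorner/
yllcorner/cellsize/NODATA_value`` header), which round-trips exactly
because values are written with full ``repr`` precision.

Presence records are CSV tables with columns ``x, y, year`` (projected
metres, integer year).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "GridGeometry",
    "SuitabilityRaster",
    "ScaledHabitatRaster",
    "CostRaster",
    "Fishnet",
    "RasterValidationError",
    "read_raster",
    "write_raster",
    "read_presences",
    "write_presences",
    "scale_suitability",
    "invert_to_cost",
    "make_fishnet",
    "round_half_away",
]

NODATA_DEFAULT = -9999.0


class RasterValidationError(ValueError):
    """Raised when raster values violate the declared expected range."""


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a regular grid in projected metres.

    ``xll, yll`` locate the lower-left corner of the grid footprint;
    internally arrays are stored with row 0 at the top (north).
    """

    nrows: int
    ncols: int
    cell_size: float
    xll: float = 0.0
    yll: float = 0.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        return (
            self.xll,
            self.yll,
            self.xll + self.ncols * self.cell_size,
            self.yll + self.nrows * self.cell_size,
        )

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.xll + (col + 0.5) * self.cell_size
        y = self.yll + (self.nrows - row - 0.5) * self.cell_size
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays of x and y coordinates of every cell centre (grid shape)."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.xll + (cols + 0.5) * self.cell_size
        y = self.yll + (self.nrows - rows - 0.5) * self.cell_size
        return np.broadcast_to(x, self.shape).copy(), np.broadcast_to(
            y[:, None], self.shape
        ).copy()

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing a projected point."""
        col = int(math.floor((x - self.xll) / self.cell_size))
        row = self.nrows - 1 - int(math.floor((y - self.yll) / self.cell_size))
        return row, col

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return xmin <= x < xmax and ymin <= y < ymax


@dataclass
class SuitabilityRaster:
    """Continuous habitat-suitability surface on a regular grid."""

    values: np.ndarray
    geometry: GridGeometry
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    crs_tag: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} != geometry {self.geometry.shape}"
            )
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError("nodata_mask shape mismatch")

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def validate_range(self, lo: float, hi: float) -> None:
        vals = self.values[self.valid_mask]
        bad = (vals < lo) | (vals > hi)
        if bad.any():
            rows, cols = np.nonzero(self.valid_mask)
            offenders = [
                (int(r), int(c), float(self.values[r, c]))
                for r, c in zip(rows[bad], cols[bad])
            ][:10]
            raise RasterValidationError(
                f"{int(bad.sum())} cell(s) outside [{lo}, {hi}]; "
                f"first offenders (row, col, value): {offenders}"
            )


@dataclass
class ScaledHabitatRaster:
    """Integer 0-100 habitat raster (suitability x 100)."""

    values: np.ndarray
    geometry: GridGeometry
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    crs_tag: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask


@dataclass
class CostRaster:
    """Positive integer movement-cost surface (same geometry as source)."""

    values: np.ndarray
    geometry: GridGeometry
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    crs_tag: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask


def round_half_away(x: np.ndarray | float) -> np.ndarray | float:
    """Round half away from zero (0.5 -> 1, -0.5 -> -1).

    Fixed rounding mode so integer scaling is platform-independent
    (numpy's default rounds half to even).
    """
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


# ---------------------------------------------------------------------------
# I/O


def _parse_ascii_header(lines: list[str]) -> tuple[dict, int]:
    header: dict[str, float] = {}
    idx = 0
    keys = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
    for idx, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in keys:
            header[parts[0].lower()] = float(parts[1])
        else:
            break
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    missing = required - header.keys()
    if missing:
        raise IOError(f"ASCII grid header missing keys: {sorted(missing)}")
    return header, idx


def read_raster(
    path: str | Path,
    expected_range: tuple[float, float] | None = (0.0, 1.0),
) -> SuitabilityRaster:
    """Read a single-band ESRI ASCII grid as a :class:`SuitabilityRaster`.

    Values on valid cells are checked against ``expected_range`` (pass
    ``None`` to skip).  Cells equal to the header's NODATA_value are
    masked.
    """
    path = Path(path)
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise IOError(f"cannot read raster {path}: {exc}") from exc
    header, body_start = _parse_ascii_header(lines)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", NODATA_DEFAULT)
    body = " ".join(lines[body_start:])
    flat = np.array(body.split(), dtype=float)
    if flat.size != nrows * ncols:
        raise IOError(
            f"ASCII grid {path}: expected {nrows * ncols} values, found {flat.size}"
        )
    values = flat.reshape(nrows, ncols)
    mask = values == nodata
    geom = GridGeometry(
        nrows=nrows,
        ncols=ncols,
        cell_size=header["cellsize"],
        xll=header["xllcorner"],
        yll=header["yllcorner"],
    )
    raster = SuitabilityRaster(values=values, geometry=geom, nodata_mask=mask)
    if expected_range is not None:
        raster.validate_range(*expected_range)
    return raster


def write_raster(
    raster: SuitabilityRaster | ScaledHabitatRaster | CostRaster,
    path: str | Path,
    nodata: float = NODATA_DEFAULT,
) -> Path:
    """Write a raster as an ESRI ASCII grid. Values round-trip exactly."""
    path = Path(path)
    g = raster.geometry
    is_int = np.issubdtype(raster.values.dtype, np.integer)
    nodata_repr = repr(int(nodata)) if is_int else repr(float(nodata))
    with path.open("w") as fh:
        fh.write(f"ncols {g.ncols}\n")
        fh.write(f"nrows {g.nrows}\n")
        fh.write(f"xllcorner {g.xll!r}\n")
        fh.write(f"yllcorner {g.yll!r}\n")
        fh.write(f"cellsize {g.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata_repr}\n")
        for r in range(g.nrows):
            row = [
                nodata_repr
                if raster.nodata_mask[r, c]
                else (repr(int(raster.values[r, c])) if is_int else repr(float(raster.values[r, c])))
                for c in range(g.ncols)
            ]
            fh.write(" ".join(row) + "\n")
    return path


def read_presences(path: str | Path) -> pd.DataFrame:
    """Read a presence table CSV with required columns x, y, year."""
    df = pd.read_csv(path)
    missing = {"x", "y", "year"} - set(df.columns)
    if missing:
        raise IOError(f"presence table {path} missing columns: {sorted(missing)}")
    df = df.copy()
    df["year"] = df["year"].astype(int)
    return df[["x", "y", "year"] + [c for c in df.columns if c not in ("x", "y", "year")]]


def write_presences(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Scalar transforms


def scale_suitability(hsm: SuitabilityRaster) -> ScaledHabitatRaster:
    """Scale unit-interval suitability to integers 0-100.

    Multiplies by 100 and rounds half away from zero; nodata preserved.
    """
    hsm.validate_range(0.0, 1.0)
    scaled = round_half_away(hsm.values * 100.0).astype(np.int64)
    scaled[hsm.nodata_mask] = 0
    return ScaledHabitatRaster(
        values=scaled,
        geometry=hsm.geometry,
        nodata_mask=hsm.nodata_mask.copy(),
        crs_tag=hsm.crs_tag,
    )


def invert_to_cost(scaled: ScaledHabitatRaster, cost_floor: int = 1) -> CostRaster:
    """Invert a 0-100 habitat raster into a movement-cost surface.

    cost = max(cost_floor, 100 - value).  The floor keeps inverse-cost
    step weights finite at maximal suitability.  Nodata cells carry the
    maximal cost (100) but are excluded from movement neighbourhoods by
    the simulator regardless.
    """
    if cost_floor < 1:
        raise ValueError("cost_floor must be >= 1")
    v = scaled.values
    if v.min() < 0 or v[scaled.valid_mask].max(initial=0) > 100:
        raise ValueError("scaled habitat values must lie in 0..100")
    cost = np.maximum(cost_floor, 100 - v).astype(np.int64)
    cost[scaled.nodata_mask] = 100
    return CostRaster(
        values=cost,
        geometry=scaled.geometry,
        nodata_mask=scaled.nodata_mask.copy(),
        crs_tag=scaled.crs_tag,
    )


# ---------------------------------------------------------------------------
# Fishnet


@dataclass(frozen=True)
class Fishnet:
    """Regular square-cell grid (e.g. 10 x 10 km) covering an extent.

    Cells are indexed (row, col) with row 0 the northernmost row, matching
    raster convention.  The net ceil-covers the extent, so edge cells may
    extend past it.
    """

    x0: float
    y0: float
    cell_size: float
    nrows: int
    ncols: int
    region_mask: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    def cell_of(self, x: float, y: float) -> tuple[int, int] | None:
        col = int(math.floor((x - self.x0) / self.cell_size))
        row_from_bottom = int(math.floor((y - self.y0) / self.cell_size))
        row = self.nrows - 1 - row_from_bottom
        if 0 <= row < self.nrows and 0 <= col < self.ncols:
            return row, col
        return None

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of a fishnet cell."""
        xmin = self.x0 + col * self.cell_size
        ymax = self.y0 + (self.nrows - row) * self.cell_size
        return (xmin, ymax - self.cell_size, xmin + self.cell_size, ymax)

    def cells(self) -> Iterator[tuple[int, int]]:
        for r in range(self.nrows):
            for c in range(self.ncols):
                if self.region_mask is None or self.region_mask[r, c]:
                    yield (r, c)

    def region_cells(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.cells())


def make_fishnet(
    extent: tuple[float, float, float, float],
    cell_size: float,
    region_mask: np.ndarray | None = None,
) -> Fishnet:
    """Build a fishnet ceil-covering ``extent`` anchored at its origin."""
    if cell_size <= 0:
        raise ValueError(f"cell_size must be > 0, got {cell_size}")
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError(f"degenerate extent {extent}")
    ncols = int(math.ceil((xmax - xmin) / cell_size - 1e-9))
    nrows = int(math.ceil((ymax - ymin) / cell_size - 1e-9))
    return Fishnet(
        x0=xmin,
        y0=ymin,
        cell_size=cell_size,
        nrows=nrows,
        ncols=ncols,
        region_mask=region_mask,
    )
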