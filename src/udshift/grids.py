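"""Co-registered raster grids and plain-text raster I/O.

Every raster-valued quantity in the package (utilization distributions,
disturbance density surfaces, elevation, habitat masks) lives on a
:class:`GridSpec` — a regular grid in a projected metric CRS.  All overlap
arithmetic requires byte-identical grids, so ``GridSpec`` is a frozen,
hashable dataclass and operations raise on mismatch rather than
resampling silently.

Array convention: ``values[i, j]`` is the cell in row *i*, column *j* with
row 0 at the **southern** edge (y increases with the row index).  ESRI
ASCII grid files store rows north-to-south; the reader/writer flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster grid (projected coordinates, meters)."""

    x0: float  # west edge
    y0: float  # south edge
    cell: float  # cell side length (m)
    n_cols: int
    n_rows: int
    crs: str = "local-metric"

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError(f"cell size must be positive, got {self.cell}")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def x_max(self) -> float:
        return self.x0 + self.cell * self.n_cols

    @property
    def y_max(self) -> float:
        return self.y0 + self.cell * self.n_rows

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area(self) -> float:
        """Cell area in m^2."""
        return self.cell * self.cell

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.n_cols) + 0.5) * self.cell

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.n_rows) + 0.5) * self.cell

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= self.x0) & (x < self.x_max) & (y >= self.y0) & (y < self.y_max)

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) indices of the cells containing the given points."""
        col = np.floor((np.asarray(x) - self.x0) / self.cell).astype(int)
        row = np.floor((np.asarray(y) - self.y0) / self.cell).astype(int)
        return row, col


@dataclass
class Raster:
    """A value surface on a :class:`GridSpec`.

    ``representation`` declares what the numbers mean so that downstream
    operations can refuse ill-typed inputs:

    - ``"density"``     probability density (m^-2), integrates to 1
    - ``"mass"``        per-cell probability mass, sums to 1
    - ``"scaled01"``    density rescaled so the maximum is 1
    - ``"proportion"``  fraction in [0, 1] (e.g. proportion disturbed)
    - ``"binary"``      {0, 1} indicator
    - ``None``          untyped (elevation, land cover, ...)
    """

    grid: GridSpec
    values: np.ndarray
    representation: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    def copy_with(self, values: np.ndarray, representation: str | None = None,
                  **meta) -> "Raster":
        return Raster(self.grid, values, representation,
                      {**self.meta, **meta})

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-cell values at point locations; NaN outside the extent."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = self.grid.contains(x, y)
        out = np.full(x.shape, np.nan)
        row, col = self.grid.cell_index(x[inside], y[inside])
        out[inside] = self.values[row, col]
        return out


def check_same_grid(*rasters: Raster) -> GridSpec:
    grids = {r.grid for r in rasters}
    if len(grids) != 1:
        raise ValueError(f"rasters are not co-registered: {len(grids)} distinct grids")
    return rasters[0].grid


def master_grid(x: np.ndarray, y: np.ndarray, cell: float, pad: float,
                crs: str = "local-metric") -> GridSpec:
    """Smallest grid covering all points padded by ``pad``, snapped to ``cell``.

    Origins are multiples of the cell size so that grids built from
    different point sets with the same cell are automatically co-registered
    wherever they overlap.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise ValueError("no points supplied")
    x0 = np.floor((x.min() - pad) / cell) * cell
    y0 = np.floor((y.min() - pad) / cell) * cell
    n_cols = int(np.ceil((x.max() + pad - x0) / cell))
    n_rows = int(np.ceil((y.max() + pad - y0) / cell))
    return GridSpec(x0, y0, cell, n_cols, n_rows, crs)


def block_mean(r: Raster, factor: int) -> Raster:
    """Aggregate by taking the mean of ``factor`` x ``factor`` blocks.

    Exact (sum-preserving up to the 1/factor^2 weight): the global mean of
    the output equals the global mean of the input.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    nr, nc = r.grid.shape
    if nr % factor or nc % factor:
        raise ValueError(
            f"grid shape {(nr, nc)} is not divisible by factor {factor}")
    v = r.values.reshape(nr // factor, factor, nc // factor, factor)
    out = v.mean(axis=(1, 3))
    grid = GridSpec(r.grid.x0, r.grid.y0, r.grid.cell * factor,
                    nc // factor, nr // factor, r.grid.crs)
    return Raster(grid, out, r.representation, dict(r.meta))


def write_ascii_grid(r: Raster, path: str | Path, nodata: float = NODATA) -> None:
    """Write an ESRI ASCII grid (.asc), rows north to south."""
    path = Path(path)
    vals = np.where(np.isnan(r.values), nodata, r.values)
    header = (
        f"ncols {r.grid.n_cols}\n"
        f"nrows {r.grid.n_rows}\n"
        f"xllcorner {r.grid.x0!r}\n"
        f"yllcorner {r.grid.y0!r}\n"
        f"cellsize {r.grid.cell!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, vals[::-1], fmt="%.10g")


def read_ascii_grid(path: str | Path, crs: str = "local-metric",
                    representation: str | None = None) -> Raster:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)[::-1].copy()
    nodata = header.get("nodata_value", NODATA)
    vals[vals == nodata] = np.nan
    grid = GridSpec(header["xllcorner"], header["yllcorner"], header["cellsize"],
                    int(header["ncols"]), int(header["nrows"]), crs)
    return Raster(grid, vals, representation)
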