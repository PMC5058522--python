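"""Anthropogenic disturbance footprints and their density surfaces.

The footprint is a set of vector features (forestry cut-blocks, roads,
well sites) each stamped with a creation year.  Features accumulate —
nothing is reclaimed — so the footprint of year *t* is the union of every
feature created in or before *t*.  The landscape-scale disturbance
surface is the proportion of disturbed habitat within a 1-km radius
(circular moving-window mean of a fine-resolution binary raster),
resampled to the 250-m analysis grid by block means, and optionally
rescaled to unit mass so it can be compared to an animal UD ("pseudo-UD").
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy.signal import fftconvolve
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .grids import GridSpec, Raster, block_mean

#: Average well-site footprint (km^2); point wells are buffered to a
#: square of this area.
WELL_BUFFER_KM2 = 0.0158

FEATURE_TYPES = ("road", "well", "cutblock")


@dataclass
class Feature:
    geometry: BaseGeometry
    type: str
    year_created: int | None


@dataclass
class FootprintSet:
    """Vector disturbance features with creation years."""

    features: list[Feature]
    crs: str = "local-metric"

    def __post_init__(self):
        missing = [i for i, f in enumerate(self.features) if f.year_created is None]
        if missing:
            raise ValueError(
                f"features without year_created at indices {missing[:10]}"
                + ("..." if len(missing) > 10 else ""))
        for f in self.features:
            if not f.geometry.is_valid:
                f.geometry = f.geometry.buffer(0)

    def __len__(self):
        return len(self.features)


def read_footprints(path: str | Path, crs: str = "local-metric") -> FootprintSet:
    """Read a GeoJSON FeatureCollection with {type, year_created} properties."""
    with Path(path).open() as fh:
        doc = json.load(fh)
    feats = []
    for f in doc["features"]:
        props = f.get("properties") or {}
        feats.append(Feature(shape(f["geometry"]), props.get("type", "cutblock"),
                             props.get("year_created")))
    return FootprintSet(feats, crs)


def write_footprints(fs: FootprintSet, path: str | Path) -> None:
    doc = {"type": "FeatureCollection", "features": [
        {"type": "Feature", "geometry": mapping(f.geometry),
         "properties": {"type": f.type, "year_created": f.year_created}}
        for f in fs.features]}
    Path(path).write_text(json.dumps(doc))


def _as_polygon(f: Feature, well_buffer_km2: float, road_width: float) -> BaseGeometry:
    geom = f.geometry
    if geom.geom_type == "Point":
        half = math.sqrt(well_buffer_km2 * 1e6) / 2.0
        return shapely.box(geom.x - half, geom.y - half, geom.x + half, geom.y + half)
    if geom.geom_type in ("LineString", "MultiLineString"):
        return geom.buffer(road_width / 2.0, cap_style="flat")
    return geom


def cumulative_footprint(fs: FootprintSet, year: int,
                         well_buffer_km2: float = WELL_BUFFER_KM2,
                         road_width: float = 20.0) -> BaseGeometry:
    """Union of all features created in or before ``year``.

    Point wells become squares of ``well_buffer_km2`` (the average well
    pad footprint); line roads are buffered to ``road_width`` meters.
    Features on the landscape before the study start are included the
    same way (cumulative semantics, no reclamation).
    """
    polys = [_as_polygon(f, well_buffer_km2, road_width)
             for f in fs.features if f.year_created <= year]
    if not polys:
        return shapely.Polygon()
    return unary_union(polys)


def rasterize(geom: BaseGeometry, grid: GridSpec) -> Raster:
    """Binary raster: 1 where the cell center falls in the geometry."""
    vals = np.zeros(grid.shape)
    if geom.is_empty:
        return Raster(grid, vals, "binary")
    geoms = getattr(geom, "geoms", [geom])
    xc, yc = grid.x_centers, grid.y_centers
    for g in geoms:
        x_min, y_min, x_max, y_max = g.bounds
        jlo, jhi = np.searchsorted(xc, [x_min, x_max])
        ilo, ihi = np.searchsorted(yc, [y_min, y_max])
        jhi = min(jhi + 1, grid.n_cols)
        ihi = min(ihi + 1, grid.n_rows)
        if jlo >= jhi or ilo >= ihi:
            continue
        xs, ys = np.meshgrid(xc[jlo:jhi], yc[ilo:ihi])
        hit = shapely.contains_xy(g, xs.ravel(), ys.ravel())
        vals[ilo:ihi, jlo:jhi] = np.maximum(vals[ilo:ihi, jlo:jhi],
                                            hit.reshape(xs.shape))
    return Raster(grid, vals, "binary")


def moving_window_density(binary: Raster, radius: float = 1000.0) -> Raster:
    """Circular moving-window mean of a binary raster.

    ``value(c)`` is the mean of the binary values over all cells whose
    centers lie within ``radius`` of the center of *c*.  Edge cells
    average over in-extent cells only (no padding), so an all-ones raster
    maps to 1 everywhere.
    """
    vals = binary.values
    uniq = np.unique(vals[np.isfinite(vals)])
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise ValueError("moving_window_density expects a binary {0,1} raster")
    cell = binary.grid.cell
    if radius < cell:
        raise ValueError(f"window radius {radius} m is below the cell size {cell} m")
    r_cells = int(radius // cell)
    off = np.arange(-r_cells, r_cells + 1)
    dy, dx = np.meshgrid(off, off, indexing="ij")
    kernel = ((dx * cell) ** 2 + (dy * cell) ** 2 <= radius**2).astype(float)
    hits = fftconvolve(vals, kernel, mode="same")
    counts = fftconvolve(np.ones_like(vals), kernel, mode="same")
    out = np.clip(hits / counts, 0.0, 1.0)
    return Raster(binary.grid, out, "proportion",
                  {**binary.meta, "window_radius_m": radius})


def resample_to_grid(dr: Raster, grid: GridSpec) -> Raster:
    """Block-mean resample onto a coarser co-registered grid.

    The target cell size must be an integer multiple of the source cell
    size and the grids must share an origin and extent; block means
    preserve the global mean exactly.
    """
    ratio = grid.cell / dr.grid.cell
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(
            f"target cell {grid.cell} is not an integer multiple of source "
            f"cell {dr.grid.cell}")
    if (dr.grid.x0, dr.grid.y0) != (grid.x0, grid.y0):
        raise ValueError("grids are not co-registered (origins differ)")
    out = block_mean(dr, int(round(ratio)))
    if out.grid != grid:
        raise ValueError(f"resampled grid {out.grid} != target grid {grid}")
    return out


def normalize_mass(dr: Raster) -> Raster:
    """Rescale a proportion raster so its cells sum to 1 (pseudo-UD)."""
    total = dr.values.sum()
    if total <= 0:
        raise ValueError(
            "zero-disturbance landscape cannot be normalized to mass; "
            "use the proportion variant only")
    return dr.copy_with(dr.values / total, "mass")


def percent_within(footprint: BaseGeometry, range_polygon: BaseGeometry,
                   radius: float = 1000.0) -> float:
    """Fraction of a range polygon within ``radius`` of a disturbance."""
    if range_polygon.area <= 0:
        raise ValueError("zero-area range polygon")
    if footprint.is_empty:
        return 0.0
    return footprint.buffer(radius).intersection(range_polygon).area / range_polygon.area


def disturbance_pseudo_ud(fs: FootprintSet, year: int, fine_grid: GridSpec,
                          coarse_grid: GridSpec, radius: float = 1000.0,
                          **kwargs) -> tuple[Raster, Raster]:
    """Footprint -> (proportion, mass) rasters on the analysis grid."""
    geom = cumulative_footprint(fs, year, **kwargs)
    binary = rasterize(geom, fine_grid)
    prop = resample_to_grid(moving_window_density(binary, radius), coarse_grid)
    prop.meta["year"] = year
    if prop.values.sum() > 0:
        mass = normalize_mass(prop)
    else:
        mass = None
    return prop, mass
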