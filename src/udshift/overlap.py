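"""Overlap indices between utilization distributions and spatial targets.

Two indices quantify the spatial relationship between a population UD and
a target surface or region:

- **PHR** — the probability mass of UD *i* inside a region (another UD's
  home range, the disturbance footprint zone, a static habitat mask).
  Directional, in [0, 1].
- **UDOI** — overlap area times the integral of the product of two UD
  densities.  Symmetric; equals 1 for two uniform UDs on the same region,
  0 for disjoint UDs, and can exceed 1 for coincident non-uniform UDs.

Everything operates on co-registered rasters; a mass below ``MASS_EPS``
is treated as zero when determining supports.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .grids import Raster, check_same_grid
from .ud import isopleth, to_mass

#: masses below this are treated as zero for support determination
MASS_EPS = 1e-12

INDEX_NAMES = ("PHR", "UDOI")
TARGETS = ("disturbance", "baseline", "alpine")


def _as_mask(region, grid=None) -> np.ndarray:
    if isinstance(region, Raster):
        if grid is not None and region.grid != grid:
            raise ValueError("region raster is not on the UD grid")
        return region.values.astype(bool)
    return np.asarray(region, dtype=bool)


def phr(ud: Raster, region) -> float:
    """Probability that the animal is inside ``region``: sum of UD mass.

    ``region`` may be a boolean array on the same grid, a binary raster,
    or a :class:`udshift.ud.HomeRange`.
    """
    m = to_mass(ud)
    if hasattr(region, "mask") and hasattr(region, "grid"):  # HomeRange
        if region.grid != m.grid:
            raise ValueError("home range is not on the UD grid")
        mask = region.mask
    else:
        mask = _as_mask(region, m.grid)
    if mask.shape != m.grid.shape:
        raise ValueError(f"mask shape {mask.shape} != grid shape {m.grid.shape}")
    return float(m.values[mask].sum())


def region_from_ud(target: Raster, rule: str = "isopleth",
                   level: float = 0.95) -> np.ndarray:
    """Boolean region mask derived from a target raster.

    - ``rule="isopleth"``: member cells of the ``level`` volume isopleth
      (used for baseline seasonal ranges);
    - ``rule="nonzero"``: cells with any positive value (for the
      disturbance surface this is "within 1 km of a feature");
    - ``rule="mask"``: the raster itself as a boolean mask (alpine).
    """
    if rule == "isopleth":
        return isopleth(target, level).mask
    if rule == "nonzero":
        eps = MASS_EPS if target.representation in ("mass", "density") else 0.0
        return target.values > eps
    if rule == "mask":
        return target.values.astype(bool)
    raise ValueError(f"unknown region rule {rule!r}")


def udoi(ud_i: Raster, ud_j: Raster, region: str = "support",
         level: float = 0.95) -> float:
    """Utilization Distribution Overlap Index between two UDs.

    ``UDOI = A_ij * sum_c f_i(c) f_j(c) a`` with *a* the cell area,
    *f* = mass / cell area, and ``A_ij`` the area of the intersection of
    the two regions: the intersection of the (positive-mass) supports by
    default, or of the ``level`` isopleths with ``region="isopleth"``.
    Symmetric in its arguments; disjoint supports give exactly 0.
    """
    grid = check_same_grid(ud_i, ud_j)
    mi, mj = to_mass(ud_i), to_mass(ud_j)
    if region == "support":
        ri = mi.values > MASS_EPS
        rj = mj.values > MASS_EPS
    elif region == "isopleth":
        ri = isopleth(mi, level).mask
        rj = isopleth(mj, level).mask
    else:
        raise ValueError(f"unknown UDOI region rule {region!r}")
    a = grid.cell_area
    area_ij = float((ri & rj).sum()) * a
    if area_ij == 0.0:
        return 0.0
    fi = mi.values / a
    fj = mj.values / a
    return area_ij * float((fi * fj).sum()) * a


def overlap_table(pop_uds: dict, disturbance_by_year: dict,
                  baselines: dict, alpine_mask: Raster | np.ndarray,
                  baseline_years: tuple[int, int] = (2006, 2013),
                  isopleth_level: float = 0.95,
                  disturbance_region: str = "nonzero") -> pd.DataFrame:
    """Long-format overlap records for every stratum.

    Parameters
    ----------
    pop_uds
        ``{(herd, season, year): mass Raster}`` population UDs.
    disturbance_by_year
        ``{year: (proportion Raster, mass Raster or None)}``.
    baselines
        ``{(herd, season): mass Raster}`` baseline-era UDs.
    alpine_mask
        Static habitat mask (boolean array or binary raster).
    baseline_years
        Inclusive year range for comparisons against the baseline range;
        UDs from the baseline era itself are not compared to it.

    Returns
    -------
    DataFrame with columns herd, season, year, index, target, value.
    """
    records = []
    base_masks = {key: region_from_ud(b, "isopleth", isopleth_level)
                  for key, b in baselines.items()}
    for (herd, season, year), ud in sorted(pop_uds.items()):
        alp = _as_mask(alpine_mask, ud.grid)
        records.append((herd, season, year, "PHR", "alpine", phr(ud, alp)))
        if year not in disturbance_by_year:
            warnings.warn(f"no disturbance raster for year {year}; "
                          f"skipping disturbance overlap for {herd}/{season}")
        else:
            prop, mass = disturbance_by_year[year]
            dist_mask = region_from_ud(prop, disturbance_region)
            records.append((herd, season, year, "PHR", "disturbance",
                            phr(ud, dist_mask)))
            if mass is not None:
                records.append((herd, season, year, "UDOI", "disturbance",
                                udoi(ud, mass)))
        if baseline_years[0] <= year <= baseline_years[1] and (herd, season) in baselines:
            records.append((herd, season, year, "PHR", "baseline",
                            phr(ud, base_masks[(herd, season)])))
            records.append((herd, season, year, "UDOI", "baseline",
                            udoi(ud, baselines[(herd, season)])))
    return pd.DataFrame(records, columns=["herd", "season", "year",
                                          "index", "target", "value"])
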