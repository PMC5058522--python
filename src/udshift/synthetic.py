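"""Synthetic landscapes, telemetry, footprints, and climate with known truth.

Real caribou telemetry of this kind is confidential, so every downstream
stage is exercised on simulated data that reproduces the study's
structure: migratory individuals with distinct low-elevation winter and
high-elevation (alpine) summer ranges, a disturbance footprint that grows
annually in the low-elevation zone, and an interannual winter-climate
index correlated with year.  The generator's parameters are the ground
truth the analysis must recover — in particular ``shift_rate``, the
per-year displacement of winter range centers toward the alpine zone, and
the fixed season onset days that drive the movement-rate schedule.

Movement follows a discrete-time mean-reverting (OU-like) random walk
toward the current season's range center: the simplest process that
yields bounded seasonal home ranges and migration bursts at season
transitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from scipy.signal import lfilter
from shapely.geometry import LineString, Point

from .disturbance import WELL_BUFFER_KM2, Feature, FootprintSet
from .grids import GridSpec, Raster, block_mean

#: Six-season schedule used throughout the synthetic study: onset
#: days-of-year for late winter, spring, calving, summer, fall, early winter.
DEFAULT_ONSETS = (36, 125, 152, 171, 281, 333)
DEFAULT_SEASON_LABELS = ("late_winter", "spring", "calving", "summer",
                         "fall", "early_winter")

CONIFER, NONFOREST, OTHER = 1, 2, 3


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

@dataclass
class LandscapeConfig:
    """Rectangular landscape with a monotone elevation gradient along +x."""

    extent: tuple[float, float, float, float] = (0.0, 0.0, 40_000.0, 40_000.0)
    fine_cell: float = 50.0
    coarse_cell: float = 250.0
    elevation_range: tuple[float, float] = (600.0, 2200.0)
    alpine_threshold: float = 1800.0
    treeline: float = 1600.0          # conifer below, nonforest above
    elevation_noise_sd: float = 25.0  # smoothed noise amplitude (m)
    other_class_frac: float = 0.03

    def __post_init__(self):
        x0, y0, x1, y1 = self.extent
        w, h = x1 - x0, y1 - y0
        if w <= 0 or h <= 0:
            raise ValueError(f"degenerate extent {self.extent}")
        for side in (w, h):
            if abs(side / self.coarse_cell - round(side / self.coarse_cell)) > 1e-9:
                raise ValueError("extent sides must be multiples of coarse_cell")
        ratio = self.coarse_cell / self.fine_cell
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("coarse_cell must be an integer multiple of fine_cell")
        lo, hi = self.elevation_range
        if not lo < self.alpine_threshold < hi:
            raise ValueError("alpine_threshold must lie inside the elevation range")

    @property
    def fine_grid(self) -> GridSpec:
        x0, y0, x1, y1 = self.extent
        return GridSpec(x0, y0, self.fine_cell,
                        int(round((x1 - x0) / self.fine_cell)),
                        int(round((y1 - y0) / self.fine_cell)))

    @property
    def coarse_grid(self) -> GridSpec:
        x0, y0, x1, y1 = self.extent
        return GridSpec(x0, y0, self.coarse_cell,
                        int(round((x1 - x0) / self.coarse_cell)),
                        int(round((y1 - y0) / self.coarse_cell)))


@dataclass
class Landscape:
    config: LandscapeConfig
    elevation: Raster   # fine grid, m a.s.l.
    alpine: Raster      # fine grid, binary
    landcover: Raster   # fine grid, classes {1 conifer, 2 nonforest, 3 other}

    @property
    def fine_grid(self) -> GridSpec:
        return self.elevation.grid

    def alpine_coarse(self) -> Raster:
        """Alpine mask on the coarse analysis grid (majority rule)."""
        factor = int(round(self.config.coarse_cell / self.config.fine_cell))
        frac = block_mean(self.alpine, factor)
        return Raster(frac.grid, (frac.values >= 0.5).astype(float), "binary")

    def alpine_boundary_x(self) -> float:
        """x-coordinate where the noise-free gradient crosses the alpine
        threshold (the western edge of the alpine zone)."""
        cfg = self.config
        lo, hi = cfg.elevation_range
        x0, _, x1, _ = cfg.extent
        return x0 + (cfg.alpine_threshold - lo) / (hi - lo) * (x1 - x0)


def make_landscape(cfg: LandscapeConfig, seed: int) -> Landscape:
    """Elevation, alpine mask, and land cover on one fine grid."""
    rng = np.random.default_rng(seed)
    grid = cfg.fine_grid
    lo, hi = cfg.elevation_range
    x0, _, x1, _ = cfg.extent
    xc = grid.x_centers
    base = lo + (hi - lo) * (xc - x0) / (x1 - x0)
    elev = np.broadcast_to(base, grid.shape).copy()
    if cfg.elevation_noise_sd > 0:
        noise = gaussian_filter(rng.standard_normal(grid.shape), sigma=3.0)
        noise *= cfg.elevation_noise_sd / max(noise.std(), 1e-12)
        elev += noise
    alpine = (elev > cfg.alpine_threshold).astype(float)
    lc = np.where(elev < cfg.treeline, CONIFER, NONFOREST).astype(float)
    speckle = rng.random(grid.shape) < cfg.other_class_frac
    lc[speckle] = OTHER
    return Landscape(cfg, Raster(grid, elev), Raster(grid, alpine, "binary"),
                     Raster(grid, lc))


# ---------------------------------------------------------------------------
# movement
# ---------------------------------------------------------------------------

@dataclass
class SeasonSpec:
    """One season of the annual schedule.

    ``center`` names which seasonal range the animals revert to;
    ``rate_scale`` multiplies the step dispersion so that seasons have
    distinct daily movement-rate levels (migration seasons are fast).
    """

    name: str
    onset_doy: int
    center: str          # "winter" or "summer"
    rate_scale: float = 1.0


def default_schedule() -> list[SeasonSpec]:
    scales = {"late_winter": 0.6, "spring": 2.5, "calving": 0.9,
              "summer": 1.3, "fall": 2.0, "early_winter": 0.75}
    centers = {"late_winter": "winter", "spring": "summer", "calving": "summer",
               "summer": "summer", "fall": "winter", "early_winter": "winter"}
    return [SeasonSpec(n, o, centers[n], scales[n])
            for n, o in zip(DEFAULT_SEASON_LABELS, DEFAULT_ONSETS)]


@dataclass
class MovementConfig:
    """Multi-year migratory movement of one herd."""

    herd: str = "A"
    n_individuals: int = 20
    years: tuple[int, int] = (1998, 2013)
    season_schedule: list[SeasonSpec] = field(default_factory=default_schedule)
    winter_center: tuple[float, float] = (16_000.0, 20_000.0)
    summer_center: tuple[float, float] = (34_000.0, 20_000.0)
    center_offset_sd: float = 2_000.0   # per-individual range-center scatter (m)
    attraction: float = 0.4             # mean-reversion rate (1/day)
    step_sd: float = 600.0              # per-step dispersion (m)
    fix_interval_hours: int = 6
    dop_lognormal: tuple[float, float] = (1.25, 0.8)  # ~90% of draws < 10
    shift_rate: float = 0.0             # winter-center drift (m/yr)
    shift_direction: tuple[float, float] = (1.0, 0.0)  # toward alpine (+x)
    attrition: float = 0.0              # per-animal-year mid-year dropout prob

    def __post_init__(self):
        onsets = [s.onset_doy for s in self.season_schedule]
        if sorted(onsets) != onsets or len(set(onsets)) != len(onsets):
            raise ValueError("season onsets must be strictly increasing")
        if not (1 <= onsets[0] and onsets[-1] <= 365):
            raise ValueError("season onsets must be days-of-year in 1..365")
        if self.shift_rate < 0:
            raise ValueError("shift_rate must be >= 0")
        if 24 % self.fix_interval_hours:
            raise ValueError("fix_interval_hours must divide 24")
        d = math.hypot(*self.shift_direction)
        if d == 0:
            raise ValueError("shift_direction must be a nonzero vector")
        self.shift_direction = (self.shift_direction[0] / d,
                                self.shift_direction[1] / d)

    def expected_winter_center(self, year: int) -> tuple[float, float]:
        """Ground-truth herd-level winter range center for a given year."""
        t = year - self.years[0]
        return (self.winter_center[0] + self.shift_rate * t * self.shift_direction[0],
                self.winter_center[1] + self.shift_rate * t * self.shift_direction[1])


def _season_of_doy(schedule: list[SeasonSpec], doy: np.ndarray) -> np.ndarray:
    """Index into the schedule for each day-of-year (wrapping segment first)."""
    onsets = np.array([s.onset_doy for s in schedule])
    idx = np.searchsorted(onsets, doy, side="right") - 1
    idx[idx < 0] = len(schedule) - 1  # before the first onset: wrapped season
    return idx


def simulate_tracks(cfg: MovementConfig, landscape: Landscape, seed: int,
                    ) -> pd.DataFrame:
    """Simulate GPS fixes for one herd.

    Positions follow an AR(1) (discretized OU) process around the current
    season's range center; winter-type centers translate by
    ``shift_rate * (season year - first year)`` along ``shift_direction``.
    Within a season instance the center is constant; the season "year" is
    the calendar year in which that instance began, so a winter spanning
    New Year keeps one center.  Per-fix DOP is lognormal; fixes are
    strictly time-ordered and clipped to the landscape extent.
    """
    x0, y0, x1, y1 = landscape.config.extent
    for c in (cfg.winter_center, cfg.summer_center):
        if not (x0 < c[0] < x1 and y0 < c[1] < y1):
            raise ValueError(f"range center {c} outside landscape extent")
    rng = np.random.default_rng(seed)
    n = cfg.n_individuals
    dt_days = cfg.fix_interval_hours / 24.0
    rho = math.exp(-cfg.attraction * dt_days)

    start = pd.Timestamp(cfg.years[0], 1, 1, tz="UTC")
    end = pd.Timestamp(cfg.years[1] + 1, 1, 1, tz="UTC")
    times = pd.date_range(start, end, freq=f"{cfg.fix_interval_hours}h",
                          inclusive="left")
    doy = np.minimum(times.dayofyear.to_numpy(), 365)
    year = times.year.to_numpy()
    sidx = _season_of_doy(cfg.season_schedule, doy)
    # season-instance year: the wrapped start-of-year segment began last year
    first_onset = cfg.season_schedule[0].onset_doy
    season_year = np.where(doy < first_onset, year - 1, year)
    season_year = np.maximum(season_year, cfg.years[0])

    offsets = {
        "winter": rng.normal(0.0, cfg.center_offset_sd, size=(n, 2)),
        "summer": rng.normal(0.0, cfg.center_offset_sd, size=(n, 2)),
    }
    base = {"winter": np.array(cfg.winter_center),
            "summer": np.array(cfg.summer_center)}
    shift_vec = np.array(cfg.shift_direction)

    # contiguous runs of constant (season, season_year)
    key = sidx * 10_000 + season_year
    run_starts = np.flatnonzero(np.r_[True, np.diff(key) != 0])
    run_ends = np.r_[run_starts[1:], len(times)]

    xs = np.empty((len(times), n, 2))
    spec0 = cfg.season_schedule[sidx[0]]
    c0 = base[spec0.center] + offsets[spec0.center]
    if spec0.center == "winter":
        c0 = c0 + cfg.shift_rate * (season_year[0] - cfg.years[0]) * shift_vec
    pos = c0.copy()  # start at the first season's center
    for s, e in zip(run_starts, run_ends):
        spec = cfg.season_schedule[sidx[s]]
        center = base[spec.center] + offsets[spec.center]
        if spec.center == "winter":
            center = center + cfg.shift_rate * (season_year[s] - cfg.years[0]) * shift_vec
        u0 = pos - center
        eps = rng.normal(0.0, cfg.step_sd * spec.rate_scale, size=(e - s, n, 2))
        zi = (rho * u0)[None]
        u, _ = lfilter([1.0], [1.0, -rho], eps, axis=0, zi=zi)
        xs[s:e] = center[None, None] + u
        pos = xs[e - 1].copy()

    np.clip(xs[..., 0], x0 + 1.0, x1 - 1.0, out=xs[..., 0])
    np.clip(xs[..., 1], y0 + 1.0, y1 - 1.0, out=xs[..., 1])

    mu, sg = cfg.dop_lognormal
    dop = rng.lognormal(mu, sg, size=(len(times), n))

    keep = np.ones((len(times), n), dtype=bool)
    if cfg.attrition > 0:
        for i in range(n):
            for yr in range(cfg.years[0], cfg.years[1] + 1):
                if rng.random() < cfg.attrition:
                    cut = rng.integers(0, len(times))
                    if year[cut] == yr:
                        keep[cut:, i] = False

    frames = []
    for i in range(n):
        m = keep[:, i]
        frames.append(pd.DataFrame({
            "animal_id": f"{cfg.herd}{i:03d}",
            "t": times[m],
            "x": xs[m, i, 0], "y": xs[m, i, 1],
            "dop": dop[m, i],
            "herd": cfg.herd,
        }))
    return pd.concat(frames, ignore_index=True)


def stationary_sd(cfg: MovementConfig, rate_scale: float = 1.0) -> float:
    """Stationary positional sd (m) of the OU walk, per axis."""
    rho = math.exp(-cfg.attraction * cfg.fix_interval_hours / 24.0)
    return cfg.step_sd * rate_scale / math.sqrt(1.0 - rho * rho)


# ---------------------------------------------------------------------------
# movement-rate profiles (segmentation ground truth)
# ---------------------------------------------------------------------------

def simulate_rate_profiles(onsets=DEFAULT_ONSETS, levels=(1.0, 5.0, 2.0, 3.0, 4.5, 1.5),
                           noise_sd: float = 0.2, n_individuals: int = 20,
                           jitter_days: int = 1, seed: int = 0,
                           ) -> list[np.ndarray]:
    """Piecewise-constant daily-rate series with known season onsets.

    Each individual's series is the circular step function defined by
    ``onsets``/``levels`` (level *i* runs from onset *i* to the next
    onset, wrapping at New Year), with integer onset jitter of up to
    ``jitter_days`` per individual and i.i.d. Gaussian noise.
    """
    if len(onsets) != len(levels):
        raise ValueError("need one level per onset")
    rng = np.random.default_rng(seed)
    onsets = np.asarray(onsets, dtype=int)
    out = []
    for _ in range(n_individuals):
        jit = onsets + rng.integers(-jitter_days, jitter_days + 1, size=onsets.size)
        days = np.arange(1, 366)
        idx = np.searchsorted(np.sort(jit), days, side="right") - 1
        order = np.argsort(jit)
        lv = np.asarray(levels, dtype=float)[order]
        series = np.where(idx < 0, lv[-1], lv[np.maximum(idx, 0)])
        series = series + rng.normal(0.0, noise_sd, size=365)
        out.append(series)
    return out


# ---------------------------------------------------------------------------
# disturbance footprint
# ---------------------------------------------------------------------------

@dataclass
class DisturbanceScenario:
    """Annually growing footprint biased to the low-elevation zone."""

    start_year: int = 1998
    end_year: int = 2013
    annual_new_area_km2: float = 10.0
    well_buffer_km2: float = WELL_BUFFER_KM2
    n_wells_per_year: int = 2
    n_cutblocks_per_year: int = 4
    road_km_per_year: float = 2.0
    road_width_m: float = 20.0
    low_elevation_quantile: float = 0.5  # features placed below this quantile
    avoid_overlap: bool = True

    def __post_init__(self):
        if self.end_year < self.start_year:
            raise ValueError("end_year before start_year")
        if self.annual_new_area_km2 < 0:
            raise ValueError("annual_new_area_km2 must be >= 0")


def simulate_footprint(scn: DisturbanceScenario, landscape: Landscape,
                       seed: int) -> FootprintSet:
    """Yearly cumulative feature set; features persist once created.

    Each year adds wells (squares of ``well_buffer_km2`` once buffered),
    one road polyline, and cut-block rectangles sized so the new feature
    area sums to ``annual_new_area_km2``; placement is rejected outside
    the low-elevation zone and (optionally) where it would overlap
    existing features.
    """
    rng = np.random.default_rng(seed)
    cfg = landscape.config
    x0, y0, x1, y1 = cfg.extent
    lo, hi = cfg.elevation_range
    x_cap = x0 + (x1 - x0) * scn.low_elevation_quantile  # gradient quantile
    placed: list = []
    features: list[Feature] = []

    def sample_box(area_m2: float, aspect: float) -> shapely.Polygon:
        w = math.sqrt(area_m2 * aspect)
        h = area_m2 / w
        for _ in range(200):
            cx = rng.uniform(x0 + w / 2, x_cap - w / 2)
            cy = rng.uniform(y0 + h / 2, y1 - h / 2)
            box = shapely.box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
            if not scn.avoid_overlap or not any(box.intersects(p) for p in placed):
                return box
        return box  # give up on non-overlap after 200 tries

    for yr in range(scn.start_year, scn.end_year + 1):
        if scn.annual_new_area_km2 == 0:
            continue
        budget = scn.annual_new_area_km2
        for _ in range(scn.n_wells_per_year):
            half = math.sqrt(scn.well_buffer_km2 * 1e6) / 2
            cx = rng.uniform(x0 + half, x_cap - half)
            cy = rng.uniform(y0 + half, y1 - half)
            features.append(Feature(Point(cx, cy), "well", yr))
            placed.append(shapely.box(cx - half, cy - half, cx + half, cy + half))
            budget -= scn.well_buffer_km2
        if scn.road_km_per_year > 0:
            length = scn.road_km_per_year * 1000.0
            ax = rng.uniform(x0 + 100, x_cap - length - 100)
            ay = rng.uniform(y0 + 100, y1 - 100)
            line = LineString([(ax, ay), (ax + length, ay)])
            features.append(Feature(line, "road", yr))
            placed.append(line.buffer(scn.road_width_m / 2, cap_style="flat"))
            budget -= scn.road_km_per_year * (scn.road_width_m / 1000.0)
        if budget > 0 and scn.n_cutblocks_per_year > 0:
            per_block = budget * 1e6 / scn.n_cutblocks_per_year
            for _ in range(scn.n_cutblocks_per_year):
                box = sample_box(per_block, aspect=rng.uniform(1.0, 2.5))
                features.append(Feature(box, "cutblock", yr))
                placed.append(box)
    return FootprintSet(features)


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------

def simulate_climate(years: tuple[int, int], r_with_year: float = 0.56,
                     seed: int = 0, mean: float = 0.0, sd: float = 1.0,
                     ) -> pd.Series:
    """NPI-like standardized winter climate index, one value per year.

    The index is built as ``r * z(year) + sqrt(1 - r^2) * noise`` with the
    noise orthogonalized against year, so the realized correlation with
    year equals ``r_with_year`` exactly (high values = cold, snowy winters).
    """
    rng = np.random.default_rng(seed)
    yrs = np.arange(years[0], years[1] + 1)
    if yrs.size == 1:
        return pd.Series([mean], index=yrs, name="npi")
    z = (yrs - yrs.mean()) / yrs.std()
    e = rng.standard_normal(yrs.size)
    e = e - e.mean() - (e @ z) / (z @ z) * z   # orthogonal to the year trend
    e /= max(e.std(), 1e-12)
    vals = r_with_year * z + math.sqrt(1 - r_with_year**2) * e
    return pd.Series(vals * sd + mean, index=yrs, name="npi")
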