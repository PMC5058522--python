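"""End-to-end orchestration: simulate/load -> filter -> seasons -> UDs ->
disturbance -> overlap -> trends, with a reproducibility manifest.

The pipeline runs from a single (YAML-able) configuration.  One master
analysis grid — the landscape's 250-m grid expanded by a padding margin —
is computed once and threaded through every stage so that UDs, baseline
ranges, disturbance surfaces, and habitat masks are co-registered by
construction.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import disturbance as dmod
from . import synthetic, telemetry, trends
from .grids import GridSpec, Raster, write_ascii_grid
from .overlap import overlap_table
from .seasons import SeasonPartition, SeasonPartitioner
from .ud import KernelUD, baseline_ud, isopleth, population_ud, scale01

logger = logging.getLogger(__name__)

STAGES = ["inputs", "filter", "seasons", "uds", "disturbance", "overlap", "trends"]


class ConfigError(ValueError):
    """Raised with the full list of configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n- " + "\n- ".join(errors))


@dataclass
class RunConfig:
    out_dir: str = "udshift_run"
    seed: int = 0
    baseline_era: tuple[int, int] = (1998, 2005)
    contemporary_era: tuple[int, int] = (2006, 2013)
    cell: float = 250.0
    fine_cell: float = 50.0
    window_radius: float = 1000.0
    isopleth_level: float = 0.95
    season_k: int = 6
    max_dop: float = 10.0
    grid_pad_cells: int = 12
    seasons: str | list = "auto"    # "auto" or [[label, onset_doy], ...]
    synthetic: dict = field(default_factory=dict)
    inputs: dict | None = None      # {telemetry, footprints, climate, ...} paths


def validate_config(raw: dict | None) -> RunConfig:
    """Normalize a raw config dict; aggregates all errors before raising."""
    raw = dict(raw or {})
    errors: list[str] = []
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in known})
    cfg.baseline_era = tuple(cfg.baseline_era)
    cfg.contemporary_era = tuple(cfg.contemporary_era)
    for name, era in (("baseline_era", cfg.baseline_era),
                      ("contemporary_era", cfg.contemporary_era)):
        if len(era) != 2 or era[1] < era[0]:
            errors.append(f"{name} must be an ordered (start, end) pair, got {era}")
    if (len(cfg.baseline_era) == 2 and len(cfg.contemporary_era) == 2
            and cfg.baseline_era[1] >= cfg.contemporary_era[0]):
        errors.append("baseline and contemporary eras must be disjoint and ordered")
    if cfg.cell <= 0 or cfg.fine_cell <= 0:
        errors.append("cell sizes must be positive")
    elif abs(cfg.cell / cfg.fine_cell - round(cfg.cell / cfg.fine_cell)) > 1e-9:
        errors.append("cell must be an integer multiple of fine_cell")
    if not 0 < cfg.isopleth_level < 1:
        errors.append(f"isopleth_level must be in (0, 1), got {cfg.isopleth_level}")
    if cfg.inputs is not None and "telemetry" not in cfg.inputs:
        errors.append("inputs block given without a telemetry path "
                      "(and no synthetic block applies)")
    if cfg.seasons != "auto":
        try:
            _partition_from_config(cfg.seasons)
        except Exception as exc:  # noqa: BLE001 - collecting all errors
            errors.append(f"invalid explicit seasons: {exc}")
    if errors:
        raise ConfigError(errors)
    return cfg


def _partition_from_config(entries) -> SeasonPartition:
    pairs = sorted(((int(o), str(lbl)) for lbl, o in entries))
    return SeasonPartition([o for o, _ in pairs], [l for _, l in pairs],
                           method="configured")


def expand_grid(grid: GridSpec, pad_cells: int) -> GridSpec:
    return GridSpec(grid.x0 - pad_cells * grid.cell, grid.y0 - pad_cells * grid.cell,
                    grid.cell, grid.n_cols + 2 * pad_cells,
                    grid.n_rows + 2 * pad_cells, grid.crs)


def embed(r: Raster, big: GridSpec, fill: float = 0.0) -> Raster:
    """Embed a raster into a larger co-registered grid, padding with ``fill``."""
    di = int(round((r.grid.y0 - big.y0) / big.cell))
    dj = int(round((r.grid.x0 - big.x0) / big.cell))
    vals = np.full(big.shape, fill)
    vals[di:di + r.grid.n_rows, dj:dj + r.grid.n_cols] = r.values
    return Raster(big, vals, r.representation, dict(r.meta))


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the full analysis; returns the output directory.

    Any stage failure aborts with the stage name and cause; outputs of
    completed stages are retained on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": _config_hash(cfg), "seed": cfg.seed,
                      "stages": {}}
    stage = "inputs"
    try:
        # -- stage 1: inputs -----------------------------------------------
        data = _stage_inputs(cfg)
        manifest["stages"]["inputs"] = {"fixes": len(data["fixes"]),
                                        "footprint_features": len(data["footprints"])}
        # -- stage 2: DOP filter -------------------------------------------
        stage = "filter"
        fixes = telemetry.filter_by_dop(data["fixes"], cfg.max_dop)
        manifest["stages"]["filter"] = {
            "fixes_in": len(data["fixes"]), "fixes_kept": len(fixes)}
        # -- stage 3: seasons ----------------------------------------------
        stage = "seasons"
        partitions = _stage_seasons(cfg, fixes, out)
        manifest["stages"]["seasons"] = {
            h: p.onsets for h, p in partitions.items()}
        # -- stage 4: UDs ---------------------------------------------------
        stage = "uds"
        grid = expand_grid(data["landscape"].config.coarse_grid, cfg.grid_pad_cells)
        uds, baselines, ind_info, skipped = _stage_uds(cfg, fixes, partitions, grid, out)
        manifest["stages"]["uds"] = {
            "population_uds": len(uds), "baselines": len(baselines),
            "individual_uds": len(ind_info), "strata_skipped_single_ud": skipped}
        # -- stage 5: disturbance ------------------------------------------
        stage = "disturbance"
        dist = _stage_disturbance(cfg, data, grid, out)
        manifest["stages"]["disturbance"] = {"years": sorted(dist)}
        # -- stage 6: overlap ----------------------------------------------
        stage = "overlap"
        alpine = embed(data["landscape"].alpine_coarse(), grid, 0.0)
        ovl = overlap_table(uds, dist, baselines, alpine,
                            baseline_years=cfg.contemporary_era,
                            isopleth_level=cfg.isopleth_level)
        ovl.to_csv(out / "overlap.csv", index=False)
        metrics = _stage_metrics(cfg, data, fixes, ind_info, dist)
        metrics.to_csv(out / "metrics.csv", index=False)
        manifest["stages"]["overlap"] = {"records": len(ovl),
                                         "metric_records": len(metrics)}
        # -- stage 7: trends -----------------------------------------------
        stage = "trends"
        tr_o = trends.overlap_trends(ovl, data["climate"],
                                     baseline_years=cfg.contemporary_era)
        tr_o.to_csv(out / "trends_overlap.csv", index=False)
        tr_m = trends.metric_trends(metrics) if len(metrics) else pd.DataFrame()
        tr_m.to_csv(out / "trends_metrics.csv", index=False)
        manifest["stages"]["trends"] = {"overlap_models": len(tr_o),
                                        "metric_models": len(tr_m)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    import udshift
    manifest["versions"] = {"udshift": udshift.__version__,
                            "numpy": np.__version__, "pandas": pd.__version__}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def _stage_inputs(cfg: RunConfig) -> dict:
    if cfg.inputs is not None:
        fixes = telemetry.read_fixes(cfg.inputs["telemetry"])
        footprints = dmod.read_footprints(cfg.inputs["footprints"])
        climate = pd.read_csv(cfg.inputs["climate"], index_col="year")["npi"]
        raise NotImplementedError(
            "loading external landscape rasters is not wired yet; "
            "use the synthetic block")  # pragma: no cover
    syn = dict(cfg.synthetic)
    rng_seed = int(syn.pop("seed", cfg.seed))
    lcfg = synthetic.LandscapeConfig(**syn.pop("landscape", {}))
    landscape = synthetic.make_landscape(lcfg, rng_seed)
    herds = syn.pop("herds", [{}])
    frames = []
    for i, herd_kwargs in enumerate(herds):
        kw = dict(herd_kwargs)
        kw.setdefault("herd", chr(ord("A") + i))
        mcfg = synthetic.MovementConfig(**kw)
        frames.append(synthetic.simulate_tracks(mcfg, landscape, rng_seed + 11 * i + 1))
    fixes = pd.concat(frames, ignore_index=True)
    yr_min = int(fixes["t"].dt.year.min())
    yr_max = int(fixes["t"].dt.year.max())
    scn = synthetic.DisturbanceScenario(
        **{"start_year": yr_min, "end_year": yr_max, **syn.pop("disturbance", {})})
    footprints = synthetic.simulate_footprint(scn, landscape, rng_seed + 101)
    climate = synthetic.simulate_climate(
        (yr_min, yr_max), seed=rng_seed + 202, **syn.pop("climate", {}))
    if syn:
        raise ConfigError([f"unknown synthetic keys: {sorted(syn)}"])
    return {"landscape": landscape, "fixes": fixes, "footprints": footprints,
            "climate": climate, "scenario": scn}


def _stage_seasons(cfg: RunConfig, fixes: pd.DataFrame, out: Path,
                   ) -> dict[str, SeasonPartition]:
    partitions: dict[str, SeasonPartition] = {}
    onset_rows = []
    for herd, hf in fixes.groupby("herd"):
        if cfg.seasons != "auto":
            partitions[herd] = _partition_from_config(cfg.seasons)
            continue
        series = [telemetry.daily_movement_rate(tr)
                  for _, tr in hf.groupby("animal_id")]
        sp = SeasonPartitioner(k=cfg.season_k).fit(series)
        partitions[herd] = sp.partition_
        for ons in sp.individual_onsets_:
            onset_rows.append({"herd": herd, "onsets": ons})
    (out / "seasons.yaml").write_text(yaml.safe_dump({
        h: {"labels": p.labels, "onsets": [int(o) for o in p.onsets]}
        for h, p in partitions.items()}))
    if onset_rows:
        pd.DataFrame(onset_rows).to_csv(out / "individual_onsets.csv", index=False)
    return partitions


def _season_instances(partition: SeasonPartition, years: range):
    for year in years:
        for label, start, end in partition.windows(year):
            yield label, year, start, end


def _stage_uds(cfg: RunConfig, fixes: pd.DataFrame,
               partitions: dict[str, SeasonPartition], grid: GridSpec,
               out: Path):
    ud_dir = out / "uds"
    ud_dir.mkdir(exist_ok=True)
    pop_uds: dict = {}
    ind_by_stratum: dict = {}
    ind_info: list[dict] = []
    skipped = 0
    years = range(int(fixes["t"].dt.year.min()), int(fixes["t"].dt.year.max()) + 1)
    for herd, hf in fixes.groupby("herd"):
        tracks = dict(tuple(hf.groupby("animal_id")))
        for label, year, start, end in _season_instances(partitions[herd], years):
            scaled = []
            for animal, tr in tracks.items():
                clipped, complete = telemetry.clip_to_season(tr, start, end)
                if not complete or len(clipped) < 50:
                    continue
                est = KernelUD(cell=cfg.cell, grid=grid).fit(
                    clipped[["x", "y"]].to_numpy())
                scaled.append(scale01(est.density_))
                hr = isopleth(est.density_, cfg.isopleth_level)
                ind_info.append({"animal_id": animal, "herd": herd,
                                 "season": label, "year": year,
                                 "start": start, "end": end,
                                 "home_range_km2": hr.area_km2, "hr": hr,
                                 "n_locations": len(clipped)})
            if len(scaled) == 1:
                skipped += 1
                continue
            if len(scaled) >= 2:
                key = (herd, label, year)
                pop_uds[key] = population_ud(scaled, herd=herd, season=label,
                                             year=year)
                ind_by_stratum[key] = scaled
                write_ascii_grid(pop_uds[key],
                                 ud_dir / f"pop_{herd}_{label}_{year}.asc")
    baselines: dict = {}
    for herd in partitions:
        for label in partitions[herd].labels:
            pool = {year: ind_by_stratum.get((herd, label, year), [])
                    for year in years}
            try:
                baselines[(herd, label)] = baseline_ud(pool, cfg.baseline_era,
                                                       herd=herd, season=label)
            except ValueError:
                continue
            write_ascii_grid(baselines[(herd, label)],
                             ud_dir / f"baseline_{herd}_{label}.asc")
    return pop_uds, baselines, ind_info, skipped


def _stage_disturbance(cfg: RunConfig, data: dict, grid: GridSpec, out: Path):
    d_dir = out / "disturbance"
    d_dir.mkdir(exist_ok=True)
    landscape = data["landscape"]
    fine = landscape.config.fine_grid
    dist: dict = {}
    yr_min = int(data["fixes"]["t"].dt.year.min())
    yr_max = int(data["fixes"]["t"].dt.year.max())
    for year in range(yr_min, yr_max + 1):
        prop, mass = dmod.disturbance_pseudo_ud(
            data["footprints"], year, fine, landscape.config.coarse_grid,
            radius=cfg.window_radius)
        prop_big = embed(prop, grid, 0.0)
        mass_big = embed(mass, grid, 0.0) if mass is not None else None
        if mass_big is not None and mass_big.values.sum() > 0:
            mass_big = mass_big.copy_with(
                mass_big.values / mass_big.values.sum(), "mass")
        dist[year] = (prop_big, mass_big)
        write_ascii_grid(prop, d_dir / f"disturbance_prop_{year}.asc")
    return dist


def _stage_metrics(cfg: RunConfig, data: dict, fixes: pd.DataFrame,
                   ind_info: list[dict], dist: dict) -> pd.DataFrame:
    landscape = data["landscape"]
    climate = data["climate"]
    rows = []
    tracks = dict(tuple(fixes.groupby("animal_id")))
    for info in ind_info:
        tr = tracks[info["animal_id"]]
        clipped, _ = telemetry.clip_to_season(tr, info["start"], info["end"])
        rates = telemetry.daily_movement_rate(clipped)
        use = trends.extract_use_metrics(clipped, landscape.elevation,
                                         landscape.landcover)
        year = info["year"]
        prop = dist[year][0] if year in dist else None
        row = {"animal_id": info["animal_id"], "herd": info["herd"],
               "season": info["season"], "year": year,
               "movement_rate": float(rates["rate"].mean()),
               "home_range_km2": info["home_range_km2"],
               "elevation": use["elevation"],
               "prop_conifer": use["prop_conifer"],
               "prop_nonforest": use["prop_nonforest"],
               "prop_disturbed": (trends.home_range_disturbed_fraction(
                   info["hr"], prop) if prop is not None else np.nan),
               "npi": float(climate.get(year, np.nan))}
        rows.append(row)
    return pd.DataFrame(rows, columns=trends.METRIC_COLUMNS)
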