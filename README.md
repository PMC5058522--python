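# udshift

Seasonal utilization distributions, disturbance pseudo-UDs, and
overlap-index trend analysis for GPS telemetry.

## The problem

Wildlife managers monitoring a population on a landscape with a growing
anthropogenic footprint (forestry cut-blocks, roads, well sites) need to
know whether the population's spatial distribution is shifting — away
from disturbed areas, away from its former range, into refuge habitat —
and whether any trend tracks industrial development or interannual
climate rather than time alone.  `udshift` implements a spatially
explicit answer for telemetry-collared, seasonally migratory ungulates
(the motivating case is mountain caribou with low-elevation winter range
and alpine summer range):

1. **Seasons** are delineated per individual by recursive partitioning of
   the daily movement-rate series against day-of-year (migration shows up
   as rate level-shifts), then aggregated to population season onsets on
   the circular year.
2. **Utilization distributions (UDs)**: for every individual × season ×
   year with complete coverage and ≥ 50 fixes (after discarding fixes
   with GPS dilution of precision ≥ 10), a fixed-kernel UD is estimated
   on a shared 250-m grid,

   `f(s) = (1/n) Σₖ φ((x_s − x_k)/h_x) φ((y_s − y_k)/h_y) / (h_x h_y)`,

   with per-axis direct plug-in (Sheather–Jones family) bandwidths.
   Individual UDs are rescaled to [0, 1], averaged cellwise into a
   population UD per herd/season/year, and renormalized to unit mass.
   A baseline-era population UD pools all individual UDs from the early
   years (default 1998–2005).
3. **Disturbance as a pseudo-UD**: the cumulative footprint of each year
   is rasterized and converted to the proportion of disturbed habitat
   within a 1-km circular moving window, resampled to the 250-m grid,
   and rescaled to sum to 1 — directly comparable to an animal UD.
4. **Overlap indices** between a population UD and a target:
   - `PHR = Σ_{s ∈ region} m(s)` — the UD's probability mass inside a
     region (disturbance zone, baseline 95% isopleth, alpine mask);
   - `UDOI = A_∩ Σ_s f_i(s) f_j(s) a` — overlap area times the integral
     of the product of two UD densities (1 for identical uniform UDs,
     0 for disjoint ones, > 1 for coincident peaked ones).
5. **Trends**: each overlap series is regressed on year and a winter
   climate index (NPI-like; high = cold, snowy winters) by OLS;
   individual metrics (movement rate, 95%-isopleth home-range size, mean
   elevation, habitat-use proportions) are modeled with linear mixed
   models (random intercept per animal, REML) against year, climate, and
   the disturbed fraction of the individual home range.

Because real telemetry of this kind is confidential, the package ships a
first-class synthetic-data module (`udshift.synthetic`) that generates
landscapes, multi-year migratory tracks with a tunable winter-range
drift toward alpine, annually growing footprints, and a climate index
correlated with year — all with known ground truth, so every stage of
the analysis is testable end to end.

## Worked example

Simulate a herd whose winter range drifts 1 km/yr toward the alpine zone,
build late-winter population UDs per year, and trend their overlap with
the baseline-era range and with alpine habitat:

```python
from udshift import synthetic
from udshift.experiments import (ShiftScenario, run_shift_replicate,
                                 centroid_drift_slope)

land = synthetic.make_landscape(synthetic.LandscapeConfig(), seed=0)
rep = run_shift_replicate(ShiftScenario(shift_rate=1000.0), seed=1,
                          landscape=land)
print(rep["series"].tail(4).round(4).to_string(index=False))
print(f"winter centroid drift: {centroid_drift_slope(rep['centroids']):.0f} m/yr")
```

```
 year    npi  phr_alpine  udoi_baseline
 2010 0.3872      0.1530         0.0407
 2011 0.1870      0.2751         0.0189
 2012 1.3315      0.5233         0.0063
 2013 1.5412      0.7178         0.0039
winter centroid drift: 999 m/yr
```

The population's winter UD progressively leaves its baseline range
(UDOI falling toward 0) and moves into alpine habitat (PHR rising to
0.72 by the final year); the recovered centroid drift matches the
simulated 1000 m/yr.  The fitted year terms carry the shift's signature:

```
UDOI(baseline) ~ year: beta = -0.1195 (95% CI -0.2550 to 0.0159)
PHR(alpine)    ~ year: beta =  0.0270 (95% CI  0.0058 to 0.0483)
```

The full pipeline (simulate/load → DOP filter → season segmentation →
UDs → disturbance surfaces → overlap table → trend tables, with a
reproducibility manifest) runs from one YAML config:

```sh
udshift run config.yaml --seed 1
udshift seasons telemetry.csv seasons.yaml --k 6
udshift filter --max-dop 10 in.csv out.csv
```

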