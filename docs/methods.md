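# Methods

This note documents the statistical model behind `udshift`, the choices
made where the design was genuinely open, and what the synthetic studies
do and do not demonstrate.

## Utilization distributions

An individual's seasonal UD is a fixed-kernel density estimate with a
Gaussian product kernel evaluated at the centers of a 250-m analysis
grid.  Cell value = density at the cell center × nothing (cells carry
density, m⁻²); mass and scaled-to-[0,1] variants are derived from it and
tracked with an explicit representation tag so that operations can
refuse ill-typed inputs (e.g., UDOI requires mass/density; the
population average requires scaled01).  The midpoint rule (center
density rather than cell-integrated kernel) under-resolves the kernel
only when h is below the cell size; with plug-in bandwidths of several
hundred meters on 250-m cells the total-mass error is below 1e-3, which
the test suite checks directly.

**Bandwidth.** Per-axis two-stage direct plug-in selection (the
Sheather–Jones family): ψ₈ from the normal-scale rule using
min(sd, IQR/1.349); ψ₆ and ψ₄ from kernel functional estimates at their
asymptotically optimal pilot bandwidths; h = (R(K)/(ψ₄ n))^{1/5}.  The
bandwidth matrix is diagonal — per-axis selection from the marginal
variances — not a full 2×2 matrix.  Density functionals are evaluated
exactly (pairwise sums) up to n = 300 and by a fine linear-binned FFT
convolution (2048 bins, relative error ~1e-4) above that; the exact path
agrees with R's `KernSmooth::dpik` to 1e-8 once dpik's own binned
approximation is run on a fine grid, and the binned path's error is far
below the sampling variability of the functional.

**Inclusion rules.** Fixes with dilution of precision ≥ 10 are discarded
(strict inequality).  A UD is estimated only from ≥ 50 fixes, and only
for individuals whose deployment spans the whole season window (±1 day
tolerance at each end; windows are half-open [start, end) so consecutive
seasons never share a fix).  Strata with a single UD are excluded from
population averaging.

**Population and baseline UDs.** Individual UDs are rescaled to max 1
(removing sample-size and fix-rate imbalance between animals), averaged
cellwise, and renormalized to unit mass.  The baseline UD pools the
scaled individual UDs of all years of the baseline era (default
1998–2005) with the same construction.  This is deliberately an average
of scaled surfaces, not a mixture of densities; the representation tag
records it, and UDOI converts via density = mass / cell area.

**Home ranges.** The 95% volume isopleth: cells ranked by value, the
shortest prefix whose cumulative mass reaches the level.  Ties at the
threshold value are broken by rank (smallest-prefix semantics, so a
uniform 100-cell UD yields a 95-cell isopleth); `ties="include"` adds
every tied cell for a conservative home range.

## Season segmentation

The daily movement rate of a track assigns each step (consecutive-fix
segment) to the calendar date of its later fix; the day's rate is total
step length over total step duration (km/day), so rate × covered span
sums exactly to the path length.  Days without an incoming step are
flagged missing.

Seasons are piecewise-constant segments of rate vs day-of-year found by
greedy recursive partitioning with a cost-complexity stopping rule: a
split is accepted only if it reduces the current total SSE by at least
5% (configurable).  The day-of-year axis is a circle — a winter spanning
New Year is one segment — so the first split places a *pair* of
boundaries (found exhaustively over all admissible pairs) and later
splits subdivide arcs.  Greedy splitting can be suboptimal beyond the
first pair; the suite verifies it stays within 5% of the exhaustive
optimum for up to three segments.  Minimum segment length defaults to 14
days.  Population onsets are the circular medians of per-individual
onsets clustered at the k largest circular gaps; the circular mean is
available by option.  k defaults to 6 seasons and is user-settable.
The exact partitioning variant, stopping rule, and aggregation statistic
are approximations chosen here and exposed as configuration, since no
canonical definition exists for this workflow.

## Disturbance surfaces

Footprint features accumulate (no reclamation): the footprint of year t
is the union of every feature created in or before t.  Point well sites
are buffered to squares of 0.0158 km² (the average well-pad footprint;
side ≈ 125.7 m); polyline roads are buffered to a 20-m width (roads'
as-built widths are rarely attributed; the value is configurable).
The union is rasterized at 50 m by the center-within-polygon rule,
averaged with a 1-km-radius circular moving window — edge cells average
over in-extent cells only, a minor effect because ranges are
interior-dominated — resampled to the 250-m grid by block means (which
preserve the global mean exactly), and optionally rescaled to unit sum
as a pseudo-UD.  The base rasterization resolution and window radius are
configuration.

## Overlap indices and trends

PHR is the UD's probability mass over a region: the disturbance zone
(cells with any disturbance within 1 km, i.e., proportion > 0 — a
threshold or isopleth rule on the pseudo-UD is configurable), the
baseline range (its 95% isopleth), or a static habitat mask.  UDOI is
the overlap area times the integral of the product of the two densities;
the overlap area defaults to the intersection of the positive-mass
supports (masses below 1e-12 are treated as zero), with a 95%-isopleth
variant available since the index is classically defined on home-range
intersections.  Comparisons against the baseline UD are made only for
contemporary-era years (default 2006–2013); baseline-era UDs are not
compared to the range they themselves define.

Overlap series are fitted per herd × season × index × target by OLS on
year and the climate index; individual metrics by a random-intercept
(per animal) linear mixed model fitted by REML, with fixed effects for
year, climate, and the disturbed fraction of the home range.  Predictor
pairs are screened by pairwise VIF = 1/(1 − r²) with a pass threshold of
3.  A coefficient is "supported" when its 95% CI excludes zero; the CI
is the fitting routine's native interval — t-based for OLS, which at the
small per-stratum n (8 annual points for baseline comparisons) has exact
coverage where a ±1.96·SE interval would be anti-conservative — with a
Wald ±1.96·SE option for comparability.  No multiple-testing correction
is applied.  The climate index of the winter ending in year Y is joined
to all seasons of year Y, which encodes the natural "following
spring/fall" lag; a lag-1 join is configuration.  Home-range-size
records more than double the largest remaining record are removed, with
the rule reapplied until stable.

## The synthetic generator

`udshift.synthetic` emulates the study conditions: a rectangular
40×40 km landscape with a monotone west–east elevation gradient
(600–2200 m), alpine above 1800 m (the eastern ~quarter), conifer below
a 1600-m treeline; two seasonal range centers per herd (low-elevation
winter in the west, alpine summer in the east); movement as a
discrete-time mean-reverting (OU-like) walk toward the current season's
center — the simplest process giving bounded seasonal home ranges and
migration bursts at the six fixed season onsets (days 36, 125, 152, 171,
281, 333); per-season step-dispersion multipliers so the daily-rate
series has distinct levels; lognormal DOP with ~90% of draws below 10 so
the quality screen is exercised without dominating; per-individual range
offsets (sd 2 km) fixed for life; and a winter-center drift of
`shift_rate` m/yr toward alpine, the ground truth for shift detection.
Default herd size is 20 collared individuals over 1998–2013 at 6-h
fixes; the OU parameters (attraction 0.4/day, step sd 600 m) give an
individual stationary positional sd of ≈1.4 km, i.e. home ranges of a
few km radius, a realistic scale for seasonal ungulate ranges.  The
footprint grows by 10 km²/yr in the low-elevation half (cut-block
rectangles, one road polyline, and two well points per year, rejected on
overlap); the climate index is built with noise orthogonalized against
year so its realized year-correlation is exactly the configured 0.56.

What the generator does *not* emulate — and hence what passing tests do
not show about field data: behavioral responses to disturbance or
predators, terrain-dependent step selection, irregular fix schedules and
habitat-biased fix failure, collar error beyond the DOP screen, partial
migration, and density dependence.  The synthetic studies validate the
estimator chain (can a known shift be recovered, at calibrated error
rates), not the ecology.

## Replicated studies and problem sizes

The shift-detection study runs 2 herds × 16 years × 20 individuals on
the 40×40 km landscape at 250-m cells (late-winter season).  Type-I
error: with `shift_rate = 0`, the year term of the baseline-UDOI
regression excludes zero in a fraction of 100 herd-replicates that must
lie in [1%, 10%] (nominal 5%).  Power: with `shift_rate = 1000` m/yr —
era centroids ~8 km apart against a ~3.5 km home-range radius — the
UDOI(baseline) year-slope is negative and the PHR(alpine) year-slope
positive in ≥ 90% of 20 replicates, and the centroid drift is recovered
within 10%.  These sizes keep the full suite around two minutes while
leaving the binomial acceptance bands comfortably wide.

## Known limitations

- No boundary correction for the KDE; grids are padded by 3 bandwidths
  and the residual leaked mass (< 1e-3) is checked, not corrected.
- No adaptive, Brownian-bridge, or autocorrelated kernel estimators;
  fixes are treated as an i.i.d. sample from the seasonal UD.
- OLS trend residuals are assumed independent across years; no temporal
  autocorrelation structure is fitted.
- The mixed models use random intercepts only (no random slopes).
- Loading external landscape rasters through the pipeline driver is not
  wired yet; the library functions accept any co-registered rasters, and
  the pipeline's synthetic mode is complete.
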