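# Methods

## The model

The package treats a prehistoric dispersal as a wave of advance: a
population front expanding from a single origin at an approximately
constant radial speed *v*, measured not in straight-line kilometres but
in *least-cost* kilometres — the length of the most time-efficient
walking route over the terrain. Under this model a site first occupied
at distance *x* from the origin lags the origin's date by *x/v* years,
so regressing time interval on distance gives a line of slope
*m = 1/v*, and the front speed is recovered by inverting the fitted
slope.

The three stages, with their assumptions:

**Chronology.** A site's date is the *oldest* acceptable radiocarbon
determination from its deposits — first arrivals, not occupation
averages. Screening keeps AMS determinations with SE ≤ 500 yr (the
bound is inclusive at 500, exclusive above), unequivocal cultural
attribution, and radiocarbon age strictly older than the cutoff
(default 27 000 ¹⁴C BP); within a site the largest ¹⁴C age wins, ties
resolved by smaller SE and then input order. Calibration is exact grid
integration: the posterior mass at calendar age τ is
exp(−(x−μ(τ))²/(2(σₓ²+σ(τ)²))) on a grid of configurable step (default
5 yr), curve values linearly interpolated. The point chronology of a
site is the *mean* of its calibrated density (the median is also
exposed). Pairwise comparisons use the full densities under
independence: the difference distribution is the discrete
cross-correlation of the two densities, summarised by a
highest-density interval (default level 0.954, the customary 2σ
reporting); the ordering probability P(A older than B) is computed by
cumulative sums with exact grid ties counted half, which makes
P(A>B) + P(B>A) = 1 an identity. These are the same mathematical
objects that MCMC-based calibration software estimates for its
Difference and Order queries, computed deterministically; no phase
models, reservoir corrections or southern-hemisphere curves are
supported.

**Terrain.** Rasters are WGS84 lon/lat grids, cell-centre registered,
row 0 northernmost; all distances are haversine great-circle lengths on
a sphere of radius 6371 km, so Earth curvature is in the calculation
without a projected grid. Slope (for map products) uses Horn's 3×3
kernel with per-latitude metre conversion of the cell sizes. Travel
cost is Tobler's hiking function, speed = 6·exp(−3.5·|s+0.05|) km/h
with s the signed slope tangent along the move — evaluated continuously
per move rather than through a per-degree lookup table, which removes
an arbitrary discretisation. Moves connect 8-neighbouring cell centres;
the move time is distance divided by the edge speed, taken as the
harmonic mean of the function at the two endpoints at the move's
tangent (the cell-boundary convention; with the tangent-only function
the two evaluations coincide). The accumulated surface solves the
single-source shortest-time problem with Dijkstra's algorithm
(`scipy.sparse.csgraph` supplies the solver; a pure-Python heap
implementation is kept as an independent cross-check). Sea and nodata
cells are impassable — the model walks around water, it does not
paddle.

Two surfaces coexist by design: the optimised quantity is *time*
(hours), but reported distances and isopleths are the *km length of the
time-optimal route*, because dispersal distances are conventionally
quoted in kilometres. Isopleths are marching-squares contours of the
length surface at multiples of 150 km.

Backlinks are canonical rather than heap-order artefacts: each cell's
predecessor is the first direction in the fixed order E, NE, N, NW, W,
SW, S, SE whose neighbour attains the cell's optimal time within 1e-9
relative tolerance. This makes backlinks, path vertices and length
accumulation bit-reproducible across platforms and directly comparable
with an exhaustive-search oracle even on flat terrain, where optimal
predecessors tie in bulk.

One monotonicity subtlety: raising elevations (adding a barrier) can
never decrease any cell's travel *time* — a theorem for shortest
paths — but it *can* decrease the km length of the time-optimal route,
by rerouting the optimum onto a slower but straighter climb. Only the
time statement is asserted as an invariant.

**Speed estimation.** Sites are first thinned to one per distance band
of width 300 km (two successive 150-km isopleths), keeping the oldest
site per band — the band's best first-arrival witness — with age ties
resolved toward the smaller distance; the origin itself is excluded.
OLS of y = t₀ − tᵢ on xᵢ follows, with the Pearson r, the standard OLS
slope SE, and a t-based confidence interval on the slope at the 80%
level used for small-sample reporting. The speed is v = 1/m with
SE(v) = SE(m)/m² (first-order delta method; note SE(v)/v = SE(m)/m
exactly). The displayed speed range is v ± SE(v) rounded half-up to two
decimals. The 1σ slope SE — not the 80% CI half-width — feeds the speed
error, because that choice reproduces the published Krems-Hundssteig
row (0.3683/0.9834² = 0.3808) to four decimals. A non-positive slope
raises an error: the front is not advancing and 1/m is meaningless.

## Packaged reference table

The packaged 25-site table carries mean calibrated ages and per-origin
least-cost distances with blanks meaning "excluded from that
regression". Fitting *all* non-blank rows of a column does not
reproduce the published slopes (e.g. 1.2303 vs the published 1.5068 for
the Geissenklosterle model) because the exact site subsets behind the
published fits are not recoverable from the printed table — many listed
sites share a distance band, and applying the one-site-per-band rule
gives yet another subset. The package therefore asserts the published
numbers only where they are arithmetically determined (slope → speed
conversion) and locks its own recomputations as frozen snapshots. Two
further source ambiguities are resolved and documented in
`demicwave.fixtures`: the Sirgenstein row's single distance is assigned
to the Krems-Hundssteig column, and the published Geissenklosterle
speed SE (0.1816) differs from the delta method applied to its own
published slope and SE (0.1846) for reasons the source does not state —
flagged, not reconciled.

## Synthetic data and what passing tests show

`make_landscape` builds a seeded DEM: a Gaussian-smoothed random field
(amplitude 150 m, correlation length 6 cells by default — rolling
hill country) plus explicit Gaussian ridges and an impassable sea band
around the border. `simulate_front` places sites uniformly over
reached land with a minimum spacing (default 50 km), sets arrival time
to least-cost distance divided by the true speed, and perturbs calendar
ages with additive Gaussian noise — the noise model reflects the
standard argument that dating error dominates distance error in this
class of estimates. Uncalibrated ages can be emitted by inverse lookup
through a synthetic curve.

The recovery study conditions mirror the scale of the real analysis: a
200×200-cell landscape at 0.2° cells (about 3 100 × 4 400 km, distances
out to ~2 500 km), true speed 0.7 km/yr, origin age 37 500 cal BP, 20
sites per replicate, dating noise σ = 300 yr, 200 replicates with the
accumulated surface computed once and sites/noise redrawn per
replicate. Under these conditions the estimator recovers the speed
exactly at σ = 0 and with |bias| < 5% at σ = 300 (observed ≈ +4%,
dominated by the oldest-per-band selection favouring negative noise
and, mildly, by Jensen's inequality in 1/m). What this does *not*
show: robustness to non-Gaussian age errors, taphonomic loss,
preferential site placement, or calibration-curve plateaus — none of
which the generator models.

A companion check demonstrates why the distance model matters: with
arrival times generated in least-cost space over ridge landscapes,
regressing on straight-line geodesic distances (shorter across a
ridge) steepens the slope and biases the recovered speed *downward*
relative to the least-cost regression — using the wrong distance
metric misestimates the front speed even with perfect dates.

## Numerical choices

- Calibration grid step 5 yr (speed/accuracy balance); density mass
  must sum to 1 within 1e-9; out-of-curve dates (beyond ±5σ slack) are
  errors naming the date.
- HPD intervals include all probability atoms tied at the inclusion
  threshold, making difference(a,b) exactly the sign-flipped reversal
  of difference(b,a).
- Dijkstra tolerances: backlink candidacy at 1e-9 relative; unreached
  cells carry time = ∞, length = NaN, backlink 0 (0 also marks the
  origin, which is distinguished by time 0).
- ESRI ASCII grids are the raster interchange format (plain text,
  square cells); GeoJSON (WGS84, lon/lat order) carries paths and
  isopleths; writers are atomic (temp file + rename).
- Rounding of displayed speed ranges is decimal half-up, two places.

## Known limitations

- No GeoTIFF I/O; production-scale DEMs must be supplied as (possibly
  resampled) ASCII grids.
- The 8-connected graph overestimates Euclidean lengths by up to ~8%
  at bearings between grid directions (octile metric); isopleth
  circularity on flat terrain is therefore asserted only at coarse
  cell sizes where the deviation is below two cell diagonals.
- Single-origin models only; no multi-origin cost allocation, no
  reaction–diffusion forward modelling, no Bayesian phase chronology.
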