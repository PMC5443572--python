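# demicwave

Wave-of-advance front-speed estimation from radiocarbon chronologies and
terrain-aware least-cost distances.

`demicwave` is built for the question archaeologists ask of a dispersal
like the Gravettian spread across Late Pleistocene Europe (~37–30 ka cal
BP): *from where, and how fast, did a population front advance?* It
implements the full estimation pipeline as a reusable Python library:

1. **Chronology** — screen radiocarbon determinations (AMS only,
   SE ≤ 500 yr, unequivocal attribution, older than a radiocarbon-age
   cutoff; oldest date per site), calibrate them by exact grid
   integration against a calibration curve, and compare calibrated dates
   through difference distributions and ordering probabilities to pick
   candidate origin sites.
2. **Terrain** — from a DEM, build Tobler hiking-function travel costs
   and compute anisotropic accumulated-cost surfaces (Dijkstra on the
   8-connected grid with a backlink raster), least-cost paths, their
   lengths in km, and kilometre isopleths.
3. **Wave speed** — thin sites to one per distance band (the oldest in
   each band), regress time interval on least-cost distance, and invert
   the slope:

   for sites at distance *xᵢ* (km) with time interval
   *yᵢ = t₀ − tᵢ* (yr) from the origin's mean calibrated age *t₀*,
   OLS gives a slope *m* (yr/km), and

   *v = 1/m* (km/yr),  *SE(v) = SE(m)/m²* (first-order delta method).

4. **Synthetic data** — seeded landscapes (relief, ridges, sea) and
   constant-speed fronts with Gaussian dating noise, so the whole
   pipeline is testable against known ground truth without downloads.

A 25-site distance/age table for the Gravettian and the corresponding
regression summaries ship as packaged fixtures.

## Worked example

`examples/03_speed_from_site_table.py` fits the two usable origin
models on the packaged table:

```
Geissenklosterle model (n=18, r=0.571):
  slope 1.2303 ± 0.4423 yr/km  -> speed 0.8128 ± 0.2923 km/yr, range 0.52-1.11
Krems-Hundssteig model (n=16, r=0.467):
  slope 0.7442 ± 0.3770 yr/km  -> speed 1.3438 ± 0.6808 km/yr, range 0.66-2.02
```

The slope is years of delay per kilometre from the origin; its
reciprocal is the front speed. Both models land in the slow, sub-
1 km/yr regime characteristic of a demic (population) dispersal rather
than a purely cultural transmission. (These fits use every non-blank
table row; the published per-model site subsets are not fully
recoverable from the printed table, so recomputed slopes differ from
the published ones — see `docs/methods.md`.)

`examples/04_recover_simulated_front.py` closes the loop on synthetic
ground truth:

```
true speed      : 0.7 km/yr
recovered speed : 0.827 ± 0.165 km/yr (n=5 band-selected sites, r=0.945)
error           : +18.1%
```

One replicate scatters around the truth; averaged over 200 seeds the
estimator's bias is under 5% at 300-yr dating noise (the test suite
checks exactly this).

The other examples cover calibration/ordering and the accumulated-cost
engine. A thin CLI (`demicwave calibrate|distances|isopleths|speed|
simulate|run-all`) wraps the same functions for shell pipelines.

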