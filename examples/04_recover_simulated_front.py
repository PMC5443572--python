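"""Round trip: simulate a dispersal front, then re-estimate its speed.

A front expanding at exactly 0.7 km/yr in least-cost space is sampled
at 20 sites with 300-yr Gaussian dating noise; the full estimator
(distances -> band selection -> regression -> slope inversion) should
land close to the true speed.
"""

import warnings

from demicwave import (
    FrontSimSpec,
    RidgeSpec,
    SiteDistanceRecord,
    SyntheticLandscapeSpec,
    accumulate_cost,
    fit_regression,
    make_landscape,
    select_band_sites,
    simulate_front,
    speed_from_fit,
)

spec = SyntheticLandscapeSpec(
    n_rows=200, n_cols=200, cell_size=0.2, relief_amplitude=300.0,
    ridges=(RidgeSpec("ns", 140, 1500.0, 5.0),), sea_fraction=0.1, seed=42,
)
dem = make_landscape(spec)
origin = dem.cell_center(100, 100)
acs = accumulate_cost(dem, origin)

fspec = FrontSimSpec(origin=origin, true_speed=0.7, origin_age=37500.0,
                     n_sites=20, age_noise_sd=300.0, seed=7)
sites = simulate_front(dem, fspec, acs=acs)

records = [
    SiteDistanceRecord(s.site_code, s.mean_cal_bp,
                       float(acs.length_km[dem.index_of(s.lon, s.lat)]))
    for s in sites
]
selected = select_band_sites(records, band_km=300.0)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # noisy ages can exceed the origin age
    fit = fit_regression(selected, fspec.origin_age)
est = speed_from_fit(fit)

print(f"true speed      : {fspec.true_speed} km/yr")
print(f"recovered speed : {est.speed:.3f} ± {est.se_speed:.3f} km/yr "
      f"(n={fit.n} band-selected sites, r={fit.r:.3f})")
print(f"error           : {100 * (est.speed / fspec.true_speed - 1):+.1f}%")
# One replicate scatters around the truth; averaged over many seeds the
# estimator is unbiased to within a few percent at this noise level.
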