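"""Front-speed estimation for a wave of advance.

The estimator follows the classic regression approach to prehistoric
dispersals: for a candidate origin, each later site contributes a point
(x, y) with x its least-cost distance from the origin (km) and y the
time interval between the origin's mean calibrated age and the site's
(years). Under a front advancing at constant speed v the points fall on
a line of slope 1/v, so ordinary least squares gives

    v = 1 / m,    SE(v) = SE(m) / m^2        (first-order delta method)

with m the fitted slope in yr/km. Before fitting, sites are thinned to
one per distance band — the band spanning two successive isopleths —
keeping the oldest site in each band, so that early outliers define the
front rather than being averaged with later re-occupations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .errors import (
    FrontNotAdvancingError,
    NoSitesError,
    ParameterError,
    SingularFitError,
)


@dataclass(frozen=True)
class SiteRecord:
    """A dated site: location plus (derived) mean calibrated age."""

    site_name: str
    site_code: str
    lon: float
    lat: float
    mean_cal_bp: float
    c14_age: float | None = None
    c14_se: float | None = None
    method: str = "AMS"
    attribution: str = ""


@dataclass(frozen=True)
class SiteDistanceRecord:
    """One regression point: a site's age and least-cost distance."""

    site_code: str
    mean_cal_bp: float
    distance_km: float

    def __post_init__(self) -> None:
        if self.distance_km < 0:
            raise ParameterError(f"{self.site_code}: distance_km must be >= 0")
        if self.mean_cal_bp <= 0:
            raise ParameterError(f"{self.site_code}: mean_cal_bp must be > 0")


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of time interval (yr) on distance (km)."""

    slope_m: float              # yr per km
    intercept: float = 0.0      # yr
    se_slope: float = 0.0       # yr per km
    r: float = 0.0
    n: int = 3
    conf_level: float = 0.80
    p_value: float = float("nan")
    ci_slope: tuple[float, float] = (float("nan"), float("nan"))


@dataclass(frozen=True)
class SpeedEstimate:
    """Front speed (km/yr) with propagated error and display range."""

    speed: float
    se_speed: float
    range: tuple[float, float]


def select_band_sites(
    records: list[SiteDistanceRecord], band_km: float = 300.0
) -> list[SiteDistanceRecord]:
    """Keep one site per distance band: the one with the oldest date.

    Bands are [k*band_km, (k+1)*band_km), k = 0, 1, ...; the default
    width of 300 km spans two successive 150-km isopleths. Ties in age
    are resolved toward the smaller distance. Output is ordered by
    distance.
    """
    if band_km <= 0:
        raise ParameterError("band_km must be positive")
    if not records:
        raise NoSitesError("no sites to select from")
    bands: dict[int, SiteDistanceRecord] = {}
    for rec in records:
        k = int(rec.distance_km // band_km)
        cur = bands.get(k)
        if (
            cur is None
            or rec.mean_cal_bp > cur.mean_cal_bp
            or (rec.mean_cal_bp == cur.mean_cal_bp and rec.distance_km < cur.distance_km)
        ):
            bands[k] = rec
    return sorted(bands.values(), key=lambda r: r.distance_km)


def fit_regression(
    selected: list[SiteDistanceRecord],
    origin_age: float,
    conf_level: float = 0.80,
) -> RegressionFit:
    """OLS of time interval on distance, with slope CI at ``conf_level``.

    y_i = origin_age - mean_cal_bp_i (years since the origin's date),
    x_i = distance_km_i. The slope standard error is the usual OLS one;
    r is the Pearson correlation of (x, y).
    """
    if not 0.0 < conf_level < 1.0:
        raise ParameterError("conf_level must lie in (0, 1)")
    if len(selected) < 3:
        raise NoSitesError(f"need at least 3 sites to fit, got {len(selected)}")
    x = np.array([r.distance_km for r in selected], dtype=float)
    y = origin_age - np.array([r.mean_cal_bp for r in selected], dtype=float)
    if np.ptp(x) == 0.0:
        raise SingularFitError("all sites at the same distance; slope undefined")
    oldest = max(r.mean_cal_bp for r in selected)
    if origin_age < oldest:
        warnings.warn(
            f"origin age {origin_age} younger than oldest selected site ({oldest})"
        )
    res = stats.linregress(x, y)
    n = x.size
    tcrit = stats.t.ppf((1.0 + conf_level) / 2.0, df=n - 2)
    return RegressionFit(
        slope_m=float(res.slope),
        intercept=float(res.intercept),
        se_slope=float(res.stderr),
        r=float(res.rvalue),
        n=n,
        conf_level=conf_level,
        p_value=float(res.pvalue),
        ci_slope=(
            float(res.slope - tcrit * res.stderr),
            float(res.slope + tcrit * res.stderr),
        ),
    )


def _round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def speed_from_fit(fit: RegressionFit) -> SpeedEstimate:
    """Convert a fitted slope (yr/km) into a front speed (km/yr).

    speed = 1/m and SE(speed) = SE(m)/m^2 (first-order delta method);
    the display range is speed ± SE rounded half-up to 2 decimals.
    """
    if not fit.slope_m > 0:
        raise FrontNotAdvancingError(
            f"slope {fit.slope_m} yr/km is not positive; front not advancing"
        )
    speed = 1.0 / fit.slope_m
    se_speed = fit.se_slope / fit.slope_m**2
    rng = (_round_half_up(speed - se_speed), _round_half_up(speed + se_speed))
    return SpeedEstimate(speed=speed, se_speed=se_speed, range=rng)


@dataclass
class OriginModelReport:
    """End-to-end result of one origin model."""

    origin: SiteRecord
    distances: list[SiteDistanceRecord]      # all reachable sites
    excluded: list[str]                      # site codes outside DEM / unreached
    selected: list[SiteDistanceRecord]       # after band selection (if applied)
    fit: RegressionFit
    speed: SpeedEstimate
    band_km: float | None = None
    paths: list = field(default_factory=list)        # LeastCostPath per site
    isopleth_lines: list = field(default_factory=list)

    def metrics(self) -> dict:
        return {
            "origin_code": self.origin.site_code,
            "n": self.fit.n,
            "slope": self.fit.slope_m,
            "se_slope": self.fit.se_slope,
            "r": self.fit.r,
            "p_value": self.fit.p_value,
            "conf_level": self.fit.conf_level,
            "ci_slope": list(self.fit.ci_slope),
            "speed": self.speed.speed,
            "se_speed": self.speed.se_speed,
            "range_lo": self.speed.range[0],
            "range_hi": self.speed.range[1],
        }


def compute_site_distances(
    origin: SiteRecord,
    sites: list[SiteRecord],
    dem,
    params=None,
    extract_paths: bool = True,
):
    """Accumulated surface plus least-cost distances to every site.

    Returns ``(acs, distances, excluded, paths)``; sites outside the DEM
    or unreached on the cost graph land in ``excluded`` (by site code)
    rather than aborting.
    """
    from . import terrain

    if params is None:
        params = terrain.ToblerParams()
    acs = terrain.accumulate_cost(dem, (origin.lon, origin.lat), params)
    grid = acs.time_raster()
    distances: list[SiteDistanceRecord] = []
    excluded: list[str] = []
    paths = []
    for s in sites:
        if s.site_code == origin.site_code:
            continue
        if not grid.contains(s.lon, s.lat):
            excluded.append(s.site_code)
            continue
        r, c = grid.index_of(s.lon, s.lat)
        if not np.isfinite(acs.time[r, c]):
            excluded.append(s.site_code)
            continue
        distances.append(
            SiteDistanceRecord(
                site_code=s.site_code,
                mean_cal_bp=s.mean_cal_bp,
                distance_km=float(acs.length_km[r, c]),
            )
        )
        if extract_paths:
            paths.append(terrain.extract_path(acs, (s.lon, s.lat)))
    return acs, distances, excluded, paths


def run_origin_model(
    origin: SiteRecord,
    sites: list[SiteRecord],
    dem,
    params=None,
    band_km: float | None = 300.0,
    conf_level: float = 0.80,
    isopleth_interval_km: float | None = 150.0,
    extract_paths: bool = True,
) -> OriginModelReport:
    """Run one full origin model: cost surface, distances, regression.

    Sites outside the DEM or unreached on the cost graph are listed in
    ``excluded`` rather than aborting the model. Band selection is
    applied when ``band_km`` is given; pass ``band_km=None`` to regress
    on every reachable site.
    """
    from . import terrain

    acs, distances, excluded, paths = compute_site_distances(
        origin, sites, dem, params=params, extract_paths=extract_paths
    )
    if not distances:
        raise NoSitesError(f"no sites reachable from origin {origin.site_code}")
    selected = (
        select_band_sites(distances, band_km) if band_km is not None else list(distances)
    )
    fit = fit_regression(selected, origin.mean_cal_bp, conf_level)
    speed = speed_from_fit(fit)
    iso = (
        terrain.isopleths(acs, isopleth_interval_km)
        if isopleth_interval_km is not None
        else []
    )
    return OriginModelReport(
        origin=origin,
        distances=distances,
        excluded=excluded,
        selected=selected,
        fit=fit,
        speed=speed,
        band_km=band_km,
        paths=paths,
        isopleth_lines=iso,
    )
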