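"""Readers and writers for the pipeline's plain-text formats.

Formats: the canonical site CSV (one radiocarbon determination per
row), the distance-table CSV (one least-cost distance column per origin
model, blank = excluded from that regression), GeoJSON for paths and
isopleths (WGS84, (lon, lat) ordering), JSON metrics reports and a
strict YAML configuration file. All writers write to a temporary file
and rename, so a failed run never leaves a partial output in place.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, fields

import pandas as pd

from .chronology import RadiocarbonDate
from .errors import ParameterError
from .terrain import Isopleth, LeastCostPath
from .wavespeed import SiteDistanceRecord, SiteRecord

SITE_COLUMNS = [
    "site", "code", "lon", "lat", "c14_age", "c14_se", "method",
    "attribution", "equivocal",
]


def _atomic_write(path, text: str) -> None:
    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_site_csv(path) -> list[RadiocarbonDate]:
    """Read the canonical site CSV into radiocarbon determinations."""
    df = pd.read_csv(path)
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"site CSV {path} missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            RadiocarbonDate(
                site_name=str(row.site),
                site_code=str(row.code),
                lon=float(row.lon),
                lat=float(row.lat),
                c14_age=float(row.c14_age),
                c14_se=float(row.c14_se),
                method=str(row.method),
                attribution=str(row.attribution),
                equivocal=_as_bool(row.equivocal),
            )
        )
    return out


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("true", "1", "yes")
    return bool(v)


def write_site_csv(dates: list[RadiocarbonDate], path) -> None:
    df = pd.DataFrame(
        [
            {
                "site": d.site_name, "code": d.site_code, "lon": d.lon,
                "lat": d.lat, "c14_age": d.c14_age, "c14_se": d.c14_se,
                "method": d.method, "attribution": d.attribution,
                "equivocal": d.equivocal,
            }
            for d in dates
        ],
        columns=SITE_COLUMNS,
    )
    _atomic_write(path, df.to_csv(index=False))


CAL_SITE_COLUMNS = ["site", "code", "lon", "lat", "mean_cal_bp"]


def read_calibrated_sites(path) -> list[SiteRecord]:
    """Read a calibrated-sites CSV (site, code, lon, lat, mean_cal_bp)."""
    df = pd.read_csv(path)
    missing = [c for c in CAL_SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"calibrated sites CSV {path} missing: {missing}")
    return [
        SiteRecord(
            site_name=str(r.site), site_code=str(r.code), lon=float(r.lon),
            lat=float(r.lat), mean_cal_bp=float(r.mean_cal_bp),
        )
        for r in df.itertuples(index=False)
    ]


def write_calibrated_sites(sites: list[SiteRecord], path) -> None:
    df = pd.DataFrame(
        [
            {"site": s.site_name, "code": s.site_code, "lon": s.lon,
             "lat": s.lat, "mean_cal_bp": s.mean_cal_bp}
            for s in sites
        ],
        columns=CAL_SITE_COLUMNS,
    )
    _atomic_write(path, df.to_csv(index=False))


def write_distance_table(
    records: dict[str, list[SiteDistanceRecord]],
    sites: list[SiteRecord],
    path,
) -> None:
    """Distance-table CSV: one ``dist_km_<origin>`` column per origin.

    ``records`` maps origin code -> distance records; a site missing
    from an origin's records gets a blank cell (excluded from that
    regression).
    """
    rows = []
    for s in sites:
        row = {"site": s.site_name, "code": s.site_code, "mean_cal_bp": s.mean_cal_bp}
        for origin_code, recs in records.items():
            by_code = {r.site_code: r.distance_km for r in recs}
            row[f"dist_km_{origin_code}"] = by_code.get(s.site_code, None)
        rows.append(row)
    df = pd.DataFrame(rows)
    _atomic_write(path, df.to_csv(index=False))


def read_distance_table(path) -> pd.DataFrame:
    """Read a distance-table CSV; blank distance cells become NaN."""
    df = pd.read_csv(path)
    for col in ("site", "code", "mean_cal_bp"):
        if col not in df.columns:
            raise ParameterError(f"distance table {path} missing column {col!r}")
    return df


def distance_records(df: pd.DataFrame, origin_code: str) -> list[SiteDistanceRecord]:
    """Non-blank rows of one origin column as regression records."""
    col = f"dist_km_{origin_code}"
    if col not in df.columns:
        raise ParameterError(f"no distance column for origin {origin_code!r}")
    out = []
    for _, row in df.iterrows():
        d = row[col]
        if pd.notna(d):
            out.append(
                SiteDistanceRecord(
                    site_code=str(row["code"]),
                    mean_cal_bp=float(row["mean_cal_bp"]),
                    distance_km=float(d),
                )
            )
    return out


def paths_to_geojson(paths: list[LeastCostPath], site_codes: list[str]) -> dict:
    feats = []
    for path, code in zip(paths, site_codes):
        feats.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[lon, lat] for lon, lat in path.vertices],
                },
                "properties": {
                    "site_code": code,
                    "time_h": path.time_h,
                    "length_km": path.length_km,
                },
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def isopleths_to_geojson(lines: list[Isopleth]) -> dict:
    feats = [
        {
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": [[lon, lat] for lon, lat in iso.vertices],
            },
            "properties": {"level_km": iso.level_km},
        }
        for iso in lines
    ]
    return {"type": "FeatureCollection", "features": feats}


def write_geojson(obj: dict, path) -> None:
    _atomic_write(path, json.dumps(obj))


def write_metrics(metrics: dict, path) -> None:
    _atomic_write(path, json.dumps(metrics, indent=2, sort_keys=True) + "\n")


@dataclass
class PipelineConfig:
    """Configuration for the end-to-end pipeline (strict keys)."""

    base_speed: float = 6.0
    steepness: float = 3.5
    offset: float = 0.05
    band_km: float = 300.0
    isopleth_interval_km: float = 150.0
    conf_level: float = 0.80
    calibration_step: float = 5.0
    hpd_level: float = 0.954
    resample_factor: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name != "seed" and v <= 0:
                raise ParameterError(f"config field {f.name} must be positive")


def read_config(path) -> PipelineConfig:
    """Read a YAML key-value config; unknown keys are rejected."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
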