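"""Packaged reference tables for the Gravettian dispersal analysis.

Two small CSVs ship with the package: the 25-row site table of mean
calibrated ages and least-cost distances from the three candidate
origin sites (Buran Kaya III in Crimea, Geissenklosterle in the Swabian
Jura, Krems-Hundssteig in Lower Austria), and the published
regression/speed summary for the two origin models with a usable
correlation. Both are checksummed on load so silent edits are caught.

One ambiguity in the source table is resolved here: the Sirgenstein row
carries a single distance (617 km) without an explicit column; it is
assigned to the Krems-Hundssteig column on geographic plausibility.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .errors import ParameterError
from .wavespeed import SiteRecord

TABLE1_SHA256 = "edcd623cd720b6be9d037ff97bef2f5fd9fbfc93f6f437e050fc62cbc0b07763"
TABLE2_SHA256 = "32274432164081ecb919af19ddfc186aa2baef770aef6952e67874cacde92770"

#: Candidate origin sites with their mean calibrated ages (years BP).
ORIGIN_CANDIDATES = {
    "BK": ("Buran Kaya", 38528.0),
    "GEISSE": ("Geissenklosterle", 37569.0),
    "KRE-H": ("Krems-Hundssteig", 37124.0),
}


def _load(name: str, expected_sha: str) -> pd.DataFrame:
    ref = resources.files("demicwave.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != expected_sha:
        raise ParameterError(
            f"packaged fixture {name} checksum mismatch ({digest})"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_table1() -> pd.DataFrame:
    """Distance/age table: columns site, code, mean_cal_bp, dist_km_<origin>."""
    return _load("table1.csv", TABLE1_SHA256)


def load_table2() -> pd.DataFrame:
    """Published regression and speed summary per origin model."""
    return _load("table2.csv", TABLE2_SHA256)


def origin_site(code: str) -> SiteRecord:
    """The origin candidate as a SiteRecord (coordinates unset: the
    packaged table carries distances, not site coordinates)."""
    if code not in ORIGIN_CANDIDATES:
        raise ParameterError(f"unknown origin code {code!r}")
    name, age = ORIGIN_CANDIDATES[code]
    return SiteRecord(site_name=name, site_code=code, lon=0.0, lat=0.0,
                      mean_cal_bp=age)
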