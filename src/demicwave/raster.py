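"""Georeferenced grid rasters and great-circle geometry.

Rasters are plain 2-D numpy arrays in geographic (WGS84 lon/lat)
coordinates, north-up and cell-centre registered: row 0 is the
northernmost row and the transform stores the centre of cell (0, 0).
Distances between cell centres are haversine great-circle distances on a
spherical Earth of radius 6371 km, so path lengths incorporate Earth
curvature without a projected grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import RasterError

EARTH_RADIUS_KM = 6371.0


@dataclass
class GridRaster:
    """A georeferenced 2-D field (elevation, slope, accumulated cost ...).

    Parameters
    ----------
    values
        Row-major array, row 0 = northernmost row.
    transform
        ``(lon0, lat0, dlon, dlat)``: centre of cell (0, 0) and positive
        cell sizes in degrees. Latitude decreases with increasing row.
    nodata_mask
        True where the cell holds no data (e.g. sea).
    units
        Free-text unit label for ``values``.
    """

    values: np.ndarray
    transform: tuple[float, float, float, float]
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise RasterError("raster values must be a 2-D array")
        lon0, lat0, dlon, dlat = self.transform
        if dlon <= 0 or dlat <= 0:
            raise RasterError("cell sizes must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise RasterError("nodata mask shape must equal values shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of a cell centre."""
        lon0, lat0, dlon, dlat = self.transform
        return (lon0 + col * dlon, lat0 - row * dlat)

    def lats(self) -> np.ndarray:
        """Latitude of each row's cell centres."""
        lon0, lat0, dlon, dlat = self.transform
        return lat0 - np.arange(self.shape[0]) * dlat

    def lons(self) -> np.ndarray:
        lon0, lat0, dlon, dlat = self.transform
        return lon0 + np.arange(self.shape[1]) * dlon

    def index_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the cell whose centre is nearest to (lon, lat).

        Raises :class:`RasterError` if the point falls outside the raster
        footprint (more than half a cell beyond the outer cell centres).
        """
        lon0, lat0, dlon, dlat = self.transform
        col = round((lon - lon0) / dlon)
        row = round((lat0 - lat) / dlat)
        nr, nc = self.shape
        if not (0 <= row < nr and 0 <= col < nc):
            raise RasterError(f"point ({lon}, {lat}) outside raster extent")
        return int(row), int(col)

    def contains(self, lon: float, lat: float) -> bool:
        try:
            self.index_of(lon, lat)
        except RasterError:
            return False
        return True


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle distance in km between (lon, lat) points, elementwise."""
    lam1, phi1, lam2, phi2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def read_esri_ascii(path, nodata_default: float = -9999.0) -> GridRaster:
    """Read an ESRI ASCII grid (.asc) into a :class:`GridRaster`.

    The format stores the lower-left corner; this is converted to the
    cell-centre registration used throughout the package. Both
    ``xllcorner`` and ``xllcenter`` header variants are accepted.
    """
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in (
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                "yllcenter", "cellsize", "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    try:
        ncols = int(header["ncols"])
        nrows = int(header["nrows"])
        cell = header["cellsize"]
    except KeyError as exc:
        raise RasterError(f"missing ESRI ASCII header field: {exc}") from exc
    nodata = header.get("nodata_value", nodata_default)
    values = np.loadtxt(data_lines, dtype=float).reshape(nrows, ncols)
    if "xllcenter" in header:
        lon0 = header["xllcenter"]
    else:
        lon0 = header["xllcorner"] + cell / 2.0
    if "yllcenter" in header:
        yll = header["yllcenter"]
    else:
        yll = header["yllcorner"] + cell / 2.0
    lat0 = yll + (nrows - 1) * cell  # centre of the top row
    mask = values == nodata
    vals = values.astype(float)
    vals[mask] = np.nan
    return GridRaster(vals, (lon0, lat0, cell, cell), nodata_mask=mask, units="m")


def write_esri_ascii(raster: GridRaster, path, nodata_value: float = -9999.0) -> None:
    """Write a :class:`GridRaster` as an ESRI ASCII grid.

    Requires square cells (the format has a single ``cellsize``).
    """
    lon0, lat0, dlon, dlat = raster.transform
    if not np.isclose(dlon, dlat):
        raise RasterError("ESRI ASCII requires square cells")
    nr, nc = raster.shape
    vals = raster.values.copy()
    vals[raster.nodata_mask] = nodata_value
    vals[~np.isfinite(vals)] = nodata_value
    with open(path, "w") as fh:
        fh.write(f"ncols {nc}\n")
        fh.write(f"nrows {nr}\n")
        fh.write(f"xllcorner {float(lon0 - dlon / 2.0):.17g}\n")
        fh.write(f"yllcorner {float(lat0 - (nr - 1) * dlat - dlat / 2.0):.17g}\n")
        fh.write(f"cellsize {float(dlon):.17g}\n")
        fh.write(f"nodata_value {float(nodata_value):.17g}\n")
        for row in vals:
            fh.write(" ".join(f"{float(v):.17g}" for v in row) + "\n")
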