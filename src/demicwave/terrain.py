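"""Terrain cost modelling: slope, hiking speed, least-cost surfaces.

The travel model is Tobler's hiking function evaluated anisotropically
on the 8-connected grid graph of a DEM: each move between neighbouring
cell centres is charged its great-circle length divided by the walking
speed at the signed slope tangent of that move. The minimum accumulated
travel time from an origin is found with Dijkstra's algorithm; alongside
the time surface the module keeps the along-path length in kilometres of
every time-optimal route and a backlink raster encoding each cell's
optimal predecessor, from which least-cost paths and kilometre isopleths
are derived.

Two surfaces therefore coexist: ``time`` (hours, the quantity optimised)
and ``length_km`` (the km length of the time-optimal route). Distances
and isopleths are reported on the length surface, so a "distance" is
always the walked length of the fastest route, not a straight line.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .errors import ParameterError, RasterError, UnreachableError
from .raster import EARTH_RADIUS_KM, GridRaster, haversine_km

#: Neighbour offsets (drow, dcol) in fixed evaluation order.
#: Backlink codes 1..8 index this list; 0 marks the origin (and
#: unreached cells, which are additionally flagged by infinite time).
DIRECTIONS: tuple[tuple[int, int], ...] = (
    (0, 1),    # 1 E
    (-1, 1),   # 2 NE
    (-1, 0),   # 3 N
    (-1, -1),  # 4 NW
    (0, -1),   # 5 W
    (1, -1),   # 6 SW
    (1, 0),    # 7 S
    (1, 1),    # 8 SE
)
_OPPOSITE = (5, 6, 7, 8, 1, 2, 3, 4)  # opposite code per code 1..8


@dataclass(frozen=True)
class ToblerParams:
    """Parameters of Tobler's hiking function.

    speed(s) = base_speed * exp(-steepness * |s + offset|), with s the
    slope tangent along the direction of travel. The default
    (6, 3.5, 0.05) gives the classic 6 km/h maximum at a slight
    (-5%) downhill grade and about 5.04 km/h on the flat.
    """

    base_speed: float = 6.0   # km/h
    steepness: float = 3.5
    offset: float = 0.05

    def __post_init__(self) -> None:
        if self.base_speed <= 0 or self.steepness <= 0 or self.offset <= 0:
            raise ParameterError("Tobler parameters must all be positive")


def tobler_speed(slope_tangent, params: ToblerParams = ToblerParams()):
    """Walking speed (km/h) at a signed slope tangent along travel."""
    s = np.asarray(slope_tangent, dtype=float)
    out = params.base_speed * np.exp(-params.steepness * np.abs(s + params.offset))
    return float(out) if out.ndim == 0 else out


def compute_slope(dem: GridRaster) -> GridRaster:
    """Slope in degrees by Horn's 3x3 finite-difference kernel.

    Cell sizes are converted from degrees to metres at each cell's own
    latitude (dy = R*dphi, dx = R*cos(phi)*dlambda, R = 6 371 000 m).
    Edges use replicated-edge padding; any cell whose 3x3 window touches
    nodata is nodata in the output.
    """
    nr, nc = dem.shape
    if nr < 3 or nc < 3:
        raise RasterError("slope needs a raster of at least 3x3 cells")
    lon0, lat0, dlon, dlat = dem.transform
    z = np.where(dem.nodata_mask, np.nan, dem.values)
    zp = np.pad(z, 1, mode="edge")
    # Horn weights (1,2,1) across the window rows/columns
    a, b, c = zp[:-2, :-2], zp[:-2, 1:-1], zp[:-2, 2:]
    d, f = zp[1:-1, :-2], zp[1:-1, 2:]
    g, h, i = zp[2:, :-2], zp[2:, 1:-1], zp[2:, 2:]
    lat = dem.lats()[:, None]
    r_m = EARTH_RADIUS_KM * 1000.0
    dx_m = r_m * np.cos(np.radians(lat)) * math.radians(dlon)
    dy_m = r_m * math.radians(dlat)
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * dx_m)
    # row index grows southward, so the "southern" row is g,h,i
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8.0 * dy_m)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    # the Horn window omits the centre cell, but a nodata cell must stay nodata
    mask = ~np.isfinite(slope) | dem.nodata_mask
    slope = np.where(mask, np.nan, slope)
    return GridRaster(slope, dem.transform, nodata_mask=mask, units="degrees")


@dataclass
class AccumulatedCostSurface:
    """Least accumulated travel time from an origin, on the DEM grid.

    ``time`` is hours (inf where unreached), ``length_km`` the walked
    length of the time-optimal route (nan where unreached), ``backlink``
    the direction code (index into :data:`DIRECTIONS`, 1-based) pointing
    from each cell toward its optimal predecessor; 0 at the origin and
    at unreached cells.
    """

    time: np.ndarray
    length_km: np.ndarray
    backlink: np.ndarray
    transform: tuple[float, float, float, float]
    origin: tuple[float, float]
    origin_rc: tuple[int, int]

    @property
    def shape(self) -> tuple[int, int]:
        return self.time.shape

    def _grid(self, values: np.ndarray, units: str) -> GridRaster:
        return GridRaster(
            values, self.transform, nodata_mask=~np.isfinite(values), units=units
        )

    def time_raster(self) -> GridRaster:
        return self._grid(self.time, "hours")

    def length_raster(self) -> GridRaster:
        return self._grid(self.length_km, "km")

    def value_at(self, lon: float, lat: float, what: str = "length_km") -> float:
        r, c = self._grid(self.time, "h").index_of(lon, lat)
        return float(getattr(self, what)[r, c])


def _move_geometry(dem: GridRaster):
    """Per-direction move distances (km) and signed slope tangents.

    Returns two lists of 8 (nr, nc) arrays: dist[d][r, c] and
    tan[d][r, c] describe the move from cell (r, c) one step in
    DIRECTIONS[d]; nan where the move leaves the raster or touches
    nodata.
    """
    nr, nc = dem.shape
    lon0, lat0, dlon, dlat = dem.transform
    lats = dem.lats()
    z = np.where(dem.nodata_mask, np.nan, dem.values)
    dists, tans = [], []
    for (dr, dc) in DIRECTIONS:
        dist = np.full((nr, nc), np.nan)
        tan = np.full((nr, nc), np.nan)
        r0, r1 = max(0, -dr), nr - max(0, dr)
        c0, c1 = max(0, -dc), nc - max(0, dc)
        src_lat = lats[r0:r1]
        dst_lat = lats[r0 + dr : r1 + dr]
        row_dist = haversine_km(0.0, src_lat, dc * dlon, dst_lat)  # (rows,)
        block = np.broadcast_to(row_dist[:, None], (r1 - r0, c1 - c0))
        dz = z[r0 + dr : r1 + dr, c0 + dc : c1 + dc] - z[r0:r1, c0:c1]
        with np.errstate(invalid="ignore", divide="ignore"):
            t = dz / (block * 1000.0)
        dist[r0:r1, c0:c1] = block
        tan[r0:r1, c0:c1] = t
        dists.append(dist)
        tans.append(tan)
    return dists, tans


def _move_times(dem: GridRaster, params: ToblerParams):
    """Per-direction move times in hours (nan = impassable move).

    The edge speed is the harmonic mean of Tobler's function evaluated
    at the move's signed tangent at both endpoints — the cell-boundary
    convention; since the function depends on the tangent alone the two
    evaluations coincide and the harmonic mean reduces to a single
    evaluation, but the convention is kept explicit for table-lookup
    variants whose speed varies per cell.
    """
    dists, tans = _move_geometry(dem)
    times = []
    for dist, tan in zip(dists, tans):
        v_src = tobler_speed(tan, params)
        v_dst = tobler_speed(tan, params)
        with np.errstate(invalid="ignore", divide="ignore"):
            v = 2.0 / (1.0 / v_src + 1.0 / v_dst)
            t = dist / v
        times.append(t)
    return dists, times


def accumulate_cost(
    dem: GridRaster,
    origin: tuple[float, float],
    params: ToblerParams = ToblerParams(),
) -> AccumulatedCostSurface:
    """Accumulated-cost surface from ``origin`` by Dijkstra on the 8-graph.

    Optimises travel time; also accumulates the km length of each
    time-optimal route and stores a canonical backlink raster. The
    backlink of a cell is the first direction, in the fixed order of
    :data:`DIRECTIONS`, whose predecessor attains the cell's optimal
    time (to within a 1e-9 relative tolerance) — a deterministic
    tie-break independent of heap order.
    """
    nr, nc = dem.shape
    if bool(dem.nodata_mask.all()):
        raise RasterError("raster is entirely nodata")
    orow, ocol = dem.index_of(*origin)
    if dem.nodata_mask[orow, ocol]:
        raise UnreachableError(f"origin {origin} lies on a nodata cell")
    dists, times = _move_times(dem, params)

    n = nr * nc
    src_idx, dst_idx, wts = [], [], []
    for d, ((dr, dc), t) in enumerate(zip(DIRECTIONS, times)):
        valid = np.isfinite(t)
        rr, cc = np.nonzero(valid)
        src_idx.append(rr * nc + cc)
        dst_idx.append((rr + dr) * nc + (cc + dc))
        wts.append(t[rr, cc])
    graph = csr_matrix(
        (np.concatenate(wts), (np.concatenate(src_idx), np.concatenate(dst_idx))),
        shape=(n, n),
    )
    time_flat = _csgraph_dijkstra(graph, indices=orow * nc + ocol)
    time = time_flat.reshape(nr, nc)
    time[dem.nodata_mask] = np.inf

    backlink = _canonical_backlinks(time, times, (orow, ocol))
    length = _accumulate_length(time, backlink, dists, (orow, ocol))
    return AccumulatedCostSurface(
        time=time,
        length_km=length,
        backlink=backlink,
        transform=dem.transform,
        origin=origin,
        origin_rc=(orow, ocol),
    )


def _canonical_backlinks(
    time: np.ndarray, move_times: list[np.ndarray], origin_rc: tuple[int, int]
) -> np.ndarray:
    """Backlink codes from an exact time surface (shared tie-break rule)."""
    nr, nc = time.shape
    cand = np.full((8, nr, nc), np.inf)
    for code in range(1, 9):
        dr, dc = DIRECTIONS[code - 1]
        move = move_times[_OPPOSITE[code - 1] - 1]  # pred -> cell move time
        r0, r1 = max(0, -dr), nr - max(0, dr)
        c0, c1 = max(0, -dc), nc - max(0, dc)
        pred_t = time[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        mt = move[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        with np.errstate(invalid="ignore"):
            cand[code - 1, r0:r1, c0:c1] = pred_t + mt
    cand[~np.isfinite(cand)] = np.inf
    best = cand.min(axis=0)
    tol = 1e-9 * np.maximum(1.0, best)
    ok = cand <= best + tol
    codes = ok.argmax(axis=0).astype(np.int16) + 1  # first direction in order
    codes[~np.isfinite(time)] = 0
    codes[~np.isfinite(best)] = 0
    codes[origin_rc] = 0
    return codes


def _accumulate_length(
    time: np.ndarray,
    backlink: np.ndarray,
    dists: list[np.ndarray],
    origin_rc: tuple[int, int],
) -> np.ndarray:
    nr, nc = time.shape
    length = np.full((nr, nc), np.nan)
    length[origin_rc] = 0.0
    reached = np.isfinite(time)
    order = np.argsort(time, axis=None, kind="stable")
    flat_bl = backlink.ravel()
    flat_len = length.ravel()
    flat_reached = reached.ravel()
    for idx in order:
        code = flat_bl[idx]
        if code == 0 or not flat_reached[idx]:
            continue
        dr, dc = DIRECTIONS[code - 1]
        r, c = divmod(int(idx), nc)
        pr, pc = r + dr, c + dc
        step = dists[_OPPOSITE[code - 1] - 1][pr, pc]
        flat_len[idx] = flat_len[pr * nc + pc] + step
    return length


@dataclass
class LeastCostPath:
    """A time-optimal route as a polyline of cell centres.

    Vertices run from the origin to the destination.
    """

    vertices: list[tuple[float, float]]
    length_km: float
    time_h: float


def extract_path(
    acs: AccumulatedCostSurface, destination: tuple[float, float]
) -> LeastCostPath:
    """Trace the backlink raster from a destination back to the origin."""
    grid = acs.time_raster()
    row, col = grid.index_of(*destination)
    if not np.isfinite(acs.time[row, col]):
        raise UnreachableError(
            f"no path: destination {destination} unreached from origin {acs.origin}"
        )
    verts = []
    r, c = row, col
    guard = acs.time.size + 1
    while True:
        verts.append(grid.cell_center(r, c))
        code = int(acs.backlink[r, c])
        if code == 0:
            break
        dr, dc = DIRECTIONS[code - 1]
        r, c = r + dr, c + dc
        guard -= 1
        if guard <= 0:  # pragma: no cover - defensive
            raise UnreachableError("backlink cycle detected")
    verts.reverse()
    return LeastCostPath(
        vertices=verts,
        length_km=float(acs.length_km[row, col]),
        time_h=float(acs.time[row, col]),
    )


@dataclass
class Isopleth:
    """One contour of equal least-cost distance from the origin."""

    level_km: float
    vertices: list[tuple[float, float]]


def isopleths(
    acs: AccumulatedCostSurface, interval_km: float = 150.0
) -> list[Isopleth]:
    """Kilometre isopleths of the least-cost length surface.

    Marching-squares contours at levels k*interval_km, k = 1, 2, ...;
    unreached and nodata cells are excluded. Returns an empty list when
    no cell reaches the first level.
    """
    from skimage import measure

    if interval_km <= 0:
        raise ParameterError("interval_km must be positive")
    surf = acs.length_km.astype(float)
    finite = np.isfinite(surf)
    if not finite.any():
        import warnings

        warnings.warn("accumulated surface entirely unreached; no isopleths")
        return []
    vmax = float(surf[finite].max())
    lon0, lat0, dlon, dlat = acs.transform
    out: list[Isopleth] = []
    masked = np.where(finite, surf, np.nan)
    k = 1
    while k * interval_km <= vmax:
        level = k * interval_km
        for contour in measure.find_contours(masked, level):
            verts = [
                (lon0 + cc * dlon, lat0 - rr * dlat) for rr, cc in contour
            ]
            if len(verts) >= 2:
                out.append(Isopleth(level_km=level, vertices=verts))
        k += 1
    return out


def dijkstra_reference(
    dem: GridRaster,
    origin: tuple[float, float],
    params: ToblerParams = ToblerParams(),
) -> AccumulatedCostSurface:
    """Heap-based Dijkstra over the same move model (pure Python).

    A second, independent route to the accumulated surface, useful for
    cross-checks; agrees with :func:`accumulate_cost` on time, backlink
    and length.
    """
    nr, nc = dem.shape
    orow, ocol = dem.index_of(*origin)
    if dem.nodata_mask[orow, ocol]:
        raise UnreachableError(f"origin {origin} lies on a nodata cell")
    dists, times = _move_times(dem, params)
    time = np.full((nr, nc), np.inf)
    time[orow, ocol] = 0.0
    heap = [(0.0, 0, orow, ocol)]
    seq = 1
    done = np.zeros((nr, nc), dtype=bool)
    while heap:
        t, _, r, c = heapq.heappop(heap)
        if done[r, c]:
            continue
        done[r, c] = True
        for d, (dr, dc) in enumerate(DIRECTIONS):
            rr, cc = r + dr, c + dc
            if not (0 <= rr < nr and 0 <= cc < nc):
                continue
            mt = times[d][r, c]
            if not np.isfinite(mt):
                continue
            nt = t + mt
            if nt < time[rr, cc]:
                time[rr, cc] = nt
                heapq.heappush(heap, (nt, seq, rr, cc))
                seq += 1
    time[dem.nodata_mask] = np.inf
    backlink = _canonical_backlinks(time, times, (orow, ocol))
    length = _accumulate_length(time, backlink, dists, (orow, ocol))
    return AccumulatedCostSurface(
        time=time,
        length_km=length,
        backlink=backlink,
        transform=dem.transform,
        origin=origin,
        origin_rc=(orow, ocol),
    )
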