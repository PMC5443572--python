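"""Slope, Tobler speeds, accumulated-cost surfaces and isopleths."""

import math

import numpy as np
import pytest

from demicwave.errors import RasterError, UnreachableError
from demicwave.raster import GridRaster, haversine_km
from demicwave.terrain import (
    ToblerParams,
    accumulate_cost,
    compute_slope,
    dijkstra_reference,
    extract_path,
    isopleths,
    tobler_speed,
)

from conftest import flat_dem
from oracles import oracle_backlinks_and_lengths

R_M = 6371000.0


def metre_cell_deg(metres=30.0):
    """Cell size in degrees whose N-S extent is `metres` at the equator."""
    return math.degrees(metres / R_M)


class TestSlope:
    def test_constant_dem_flat(self):
        dem = flat_dem(8, 8)
        slope = compute_slope(dem)
        assert np.allclose(slope.values, 0.0)

    def test_plane_rising_one_per_one_northing_is_45deg(self):
        cell = metre_cell_deg(100.0)
        nr, nc = 9, 9
        rows = np.arange(nr)[:, None]
        # row 0 is north; rise 100 m per 100 m of northing
        vals = np.broadcast_to((nr - 1 - rows) * 100.0, (nr, nc)).copy()
        dem = GridRaster(vals, (0.0, 0.0, cell, cell))
        slope = compute_slope(dem)
        assert np.allclose(slope.values[1:-1, 1:-1], 45.0, atol=1e-6)

    def test_hand_evaluated_horn_kernel(self):
        cell = metre_cell_deg(30.0)
        vals = np.array([[0.0, 0, 0], [0, 0, 0], [30, 30, 30]])
        dem = GridRaster(vals, (0.0, 0.0, cell, cell))
        slope = compute_slope(dem)
        # Horn at the centre: dz/dx = 0;
        # dz/dy = ((30+2*30+30) - (0+0+0)) / (8*30) = 0.5
        assert slope.values[1, 1] == pytest.approx(math.degrees(math.atan(0.5)),
                                                   abs=1e-6)

    def test_too_small_raster_rejected(self):
        with pytest.raises(RasterError):
            compute_slope(flat_dem(2, 5))

    def test_nodata_propagates(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[4, 4] = True
        slope = compute_slope(flat_dem(8, 8, mask=mask))
        assert slope.nodata_mask[3:6, 3:6].all()
        assert not slope.nodata_mask[0, 0]


class TestToblerSpeed:
    def test_maximum_at_slight_downhill(self):
        assert tobler_speed(-0.05) == pytest.approx(6.0)

    def test_flat_ground_value(self):
        assert tobler_speed(0.0) == pytest.approx(6.0 * math.exp(-0.175), rel=1e-12)

    @pytest.mark.parametrize("s", [-0.3, -0.1, 0.0, 0.07, 0.4])
    def test_reflection_symmetry_about_offset(self, s):
        assert tobler_speed(s) == pytest.approx(tobler_speed(-0.10 - s), rel=1e-12)


class TestAccumulateCost:
    def test_origin_cell_zeroed(self):
        dem = flat_dem(16, 16)
        acs = accumulate_cost(dem, dem.cell_center(8, 8))
        assert acs.time[8, 8] == 0.0
        assert acs.length_km[8, 8] == 0.0
        assert acs.backlink[8, 8] == 0

    def test_flat_dem_uniform_speed_due_east(self):
        dem = flat_dem(21, 21, cell=0.1)
        acs = accumulate_cost(dem, dem.cell_center(10, 10))
        target = dem.cell_center(10, 17)
        d = haversine_km(*dem.cell_center(10, 10), *target)
        cell_diag = haversine_km(*dem.cell_center(10, 10), *dem.cell_center(11, 11))
        assert acs.length_km[10, 17] == pytest.approx(d, abs=cell_diag)
        assert acs.time[10, 17] == pytest.approx(
            acs.length_km[10, 17] / tobler_speed(0.0), rel=1e-9
        )

    def test_origin_on_nodata_rejected(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[8, 8] = True
        dem = flat_dem(16, 16, mask=mask)
        with pytest.raises(UnreachableError):
            accumulate_cost(dem, dem.cell_center(8, 8))

    def test_all_nodata_rejected(self):
        mask = np.ones((16, 16), dtype=bool)
        with pytest.raises(RasterError):
            accumulate_cost(flat_dem(16, 16, mask=mask), (0.0, 50.0))

    def test_barrier_grid_matches_bruteforce(self, rng):
        # 7x7 with an impassable middle column except one gap
        mask = np.zeros((7, 7), dtype=bool)
        mask[:, 3] = True
        mask[5, 3] = False
        vals = rng.uniform(0, 400, size=(7, 7))
        vals[mask] = np.nan
        dem = GridRaster(vals, (0.0, 45.0, 0.05, 0.05), nodata_mask=mask)
        acs = accumulate_cost(dem, dem.cell_center(3, 0))
        t, bl, ln = oracle_backlinks_and_lengths(dem, (3, 0))
        assert np.allclose(acs.time, t, rtol=1e-9, equal_nan=True)
        assert (acs.backlink == bl).all()
        assert np.allclose(acs.length_km, ln, rtol=1e-9, equal_nan=True)

    def test_reference_dijkstra_agrees(self, rng):
        vals = rng.uniform(0, 800, size=(12, 12))
        dem = GridRaster(vals, (5.0, 40.0, 0.08, 0.08))
        origin = dem.cell_center(6, 6)
        a = accumulate_cost(dem, origin)
        b = dijkstra_reference(dem, origin)
        assert np.allclose(a.time, b.time, rtol=1e-9)
        assert (a.backlink == b.backlink).all()

    def test_triangle_inequality_on_random_grid(self, rng):
        vals = rng.uniform(0, 500, size=(20, 20))
        dem = GridRaster(vals, (0.0, 48.0, 0.05, 0.05))
        o = dem.cell_center(10, 10)
        acs_o = accumulate_cost(dem, o)
        for _ in range(5):
            ar, ac = rng.integers(0, 20, size=2)
            acs_a = accumulate_cost(dem, dem.cell_center(ar, ac))
            lhs = acs_o.time
            rhs = acs_o.time[ar, ac] + acs_a.time
            assert (lhs <= rhs + 1e-9).all()

    def test_barrier_never_shortens(self, rng):
        base = rng.uniform(0, 200, size=(15, 15))
        dem = GridRaster(base, (0.0, 46.0, 0.05, 0.05))
        ridge = base.copy()
        ridge[:, 7] += 2500.0  # mountain wall between origin and east half
        dem_r = GridRaster(ridge, (0.0, 46.0, 0.05, 0.05))
        o = dem.cell_center(7, 2)
        a0 = accumulate_cost(dem, o)
        a1 = accumulate_cost(dem_r, o)
        assert (a1.time >= a0.time - 1e-9).all()


class TestExtractPath:
    def test_destination_equals_origin(self):
        dem = flat_dem(16, 16)
        o = dem.cell_center(8, 8)
        path = extract_path(accumulate_cost(dem, o), o)
        assert path.vertices == [o]
        assert path.length_km == 0.0

    def test_flat_dem_straight_line_east(self):
        dem = flat_dem(16, 16, cell=0.1)
        o = dem.cell_center(8, 2)
        acs = accumulate_cost(dem, o)
        path = extract_path(acs, dem.cell_center(8, 12))
        lats = {lat for _, lat in path.vertices}
        assert len(lats) == 1  # never leaves the row
        assert len(path.vertices) == 11

    def test_matches_oracle_path_on_barrier_grid(self, rng):
        mask = np.zeros((7, 7), dtype=bool)
        mask[:, 3] = True
        mask[1, 3] = False
        vals = rng.uniform(0, 300, size=(7, 7))
        vals[mask] = np.nan
        dem = GridRaster(vals, (0.0, 52.0, 0.05, 0.05), nodata_mask=mask)
        acs = accumulate_cost(dem, dem.cell_center(3, 0))
        _, bl, _ = oracle_backlinks_and_lengths(dem, (3, 0))
        # walk the oracle backlinks from the far corner
        from demicwave.terrain import DIRECTIONS

        r, c = 3, 6
        oracle_verts = []
        while True:
            oracle_verts.append(dem.cell_center(r, c))
            if bl[r, c] == 0:
                break
            dr, dc = DIRECTIONS[bl[r, c] - 1]
            r, c = r + dr, c + dc
        path = extract_path(acs, dem.cell_center(3, 6))
        assert path.vertices == oracle_verts[::-1]

    def test_unreached_destination_raises(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[:, 8] = True  # unbroken wall
        dem = flat_dem(16, 16, mask=mask)
        acs = accumulate_cost(dem, dem.cell_center(8, 2))
        with pytest.raises(UnreachableError, match="no path"):
            extract_path(acs, dem.cell_center(8, 14))

    def test_time_strictly_decreases_toward_origin(self, rng):
        vals = rng.uniform(0, 600, size=(15, 15))
        dem = GridRaster(vals, (0.0, 44.0, 0.06, 0.06))
        acs = accumulate_cost(dem, dem.cell_center(7, 7))
        grid = acs.time_raster()
        path = extract_path(acs, dem.cell_center(0, 14))
        times = [acs.time[grid.index_of(lon, lat)] for lon, lat in path.vertices]
        assert all(t1 > t0 for t0, t1 in zip(times, times[1:]))


class TestIsopleths:
    def test_flat_isopleths_are_circular(self):
        dem = flat_dem(41, 41, cell=0.25, lat0=50.0)
        o = dem.cell_center(20, 20)
        acs = accumulate_cost(dem, o)
        lines = isopleths(acs, 150.0)
        assert lines
        diag = haversine_km(*dem.cell_center(20, 20), *dem.cell_center(21, 21))
        for iso in lines:
            radii = np.array(
                [haversine_km(lon, lat, o[0], o[1]) for lon, lat in iso.vertices]
            )
            assert np.abs(radii - iso.level_km).max() < 2 * diag

    def test_interval_beyond_surface_empty(self):
        dem = flat_dem(16, 16, cell=0.05)
        acs = accumulate_cost(dem, dem.cell_center(8, 8))
        assert isopleths(acs, 10000.0) == []

    def test_levels_increasing_multiples_of_interval(self):
        dem = flat_dem(33, 33, cell=0.2)
        acs = accumulate_cost(dem, dem.cell_center(16, 16))
        lines = isopleths(acs, 100.0)
        levels = sorted({iso.level_km for iso in lines})
        assert levels == [100.0 * (k + 1) for k in range(len(levels))]
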