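import math

import numpy as np
import pytest

import phyloldg as pl
from phyloldg.covariates import GridLayer


class TestTopographicRoughness:
    def test_flat_terrain_is_unity(self):
        assert pl.topographic_roughness(0.0) == 1.0

    def test_sixty_degrees_doubles(self):
        assert pl.topographic_roughness(60.0) == pytest.approx(2.0, abs=1e-12)

    def test_forty_five_degrees_is_sqrt2(self):
        assert pl.topographic_roughness(45.0) == pytest.approx(math.sqrt(2), abs=1e-6)

    def test_strictly_increasing(self):
        grid = np.linspace(0, 89.9, 1000)
        tr = pl.topographic_roughness(grid)
        assert np.all(np.diff(tr) > 0)
        assert np.all(tr >= 1.0)

    @pytest.mark.parametrize("bad", [-0.1, 90.0, 95.0])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            pl.topographic_roughness(bad)


class TestSlopeFromDem:
    def test_constant_dem_is_flat(self):
        dem = GridLayer(np.full((5, 5), 42.0), cellsize=10.0)
        assert np.allclose(pl.slope_from_dem(dem).values, 0.0)

    def test_unit_plane_gives_45_degrees(self):
        x = np.arange(7, dtype=float)
        dem = GridLayer(np.tile(x, (7, 1)), cellsize=1.0)
        slope = pl.slope_from_dem(dem).values
        assert np.allclose(slope[1:-1, 1:-1], 45.0, atol=1e-9)

    def test_diagonal_plane_gives_atan_sqrt2(self):
        x = np.arange(7, dtype=float)
        dem = GridLayer(x[None, :] + x[:, None], cellsize=1.0)
        slope = pl.slope_from_dem(dem).values
        expected = math.degrees(math.atan(math.sqrt(2)))
        assert np.allclose(slope[1:-1, 1:-1], expected, atol=1e-9)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="3x3"):
            pl.slope_from_dem(GridLayer(np.zeros((2, 5))))

    def test_nodata_cells_masked_in_output(self):
        z = np.full((5, 5), 10.0)
        z[2, 2] = -9999.0
        out = pl.slope_from_dem(GridLayer(z, nodata=-9999.0))
        assert out.values[2, 2] == -9999.0
        assert not out.mask[2, 2]


class TestClimateIndices:
    def test_constant_precipitation_sums(self):
        mc = pl.MonthlyClimate(np.arange(1, 13, dtype=float), np.full(12, 100.0))
        idx = pl.climate_indices(mc)
        assert idx["MAP"] == pytest.approx(1200.0)
        assert idx["MTCM"] == pytest.approx(1.0)
        assert idx["MAT"] == pytest.approx(6.5)

    def test_constant_cold_climate(self):
        mc = pl.MonthlyClimate(np.full(12, -5.0), np.zeros(12))
        idx = pl.climate_indices(mc)
        assert idx["MTCM"] == -5.0 and idx["MAP"] == 0.0

    def test_invariant_to_month_reordering(self):
        rng = np.random.default_rng(0)
        t, p = rng.normal(10, 8, 12), rng.gamma(2, 40, 12)
        perm = rng.permutation(12)
        a = pl.climate_indices(pl.MonthlyClimate(t, p))
        b = pl.climate_indices(pl.MonthlyClimate(t[perm], p[perm]))
        assert all(a[k] == pytest.approx(b[k]) for k in ("MAP", "MTCM", "MAT"))

    def test_negative_precipitation_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            pl.MonthlyClimate(np.zeros(12), np.full(12, -1.0))

    def test_wrong_month_count_rejected(self):
        with pytest.raises(ValueError, match="12"):
            pl.MonthlyClimate(np.zeros(11), np.zeros(11))


class TestAnomaly:
    @pytest.mark.parametrize("cur,lgm,expected", [(5.0, -3.0, 8.0),
                                                  (2.0, 2.0, 0.0),
                                                  (-2.0, 1.0, -3.0)])
    def test_mat_difference(self, cur, lgm, expected):
        current = pl.MonthlyClimate(np.full(12, cur), np.zeros(12), era="current")
        glacial = pl.MonthlyClimate(np.full(12, lgm), np.zeros(12), era="LGM")
        assert pl.anomaly(current, glacial) == pytest.approx(expected)

    def test_swapped_eras_rejected(self):
        cur = pl.MonthlyClimate(np.zeros(12), np.zeros(12), era="current")
        lgm = pl.MonthlyClimate(np.zeros(12), np.zeros(12), era="LGM")
        with pytest.raises(ValueError, match="swapped"):
            pl.anomaly(lgm, cur)


class TestNdviAnnual:
    def _month(self, *vals):
        return [np.array([[v]]) for v in vals]

    def test_constant_months(self):
        year = [self._month(0.3, 0.5, 0.4)] * 12
        assert pl.ndvi_annual([year]) == pytest.approx(0.5)

    def test_mean_of_monthly_maxima(self):
        year = [self._month(0.1)] * 6 + [self._month(0.7)] * 6
        assert pl.ndvi_annual([year]) == pytest.approx(0.4)

    def test_spatial_mean_over_cells(self):
        cell = np.array([[0.2, 0.6]])
        year = [[cell]] * 12
        assert pl.ndvi_annual([year]) == pytest.approx(0.4)

    def test_invariant_to_dekad_order(self):
        rng = np.random.default_rng(1)
        months = [[rng.random((3, 3)) for _ in range(3)] for _ in range(12)]
        shuffled = [list(reversed(m)) for m in months]
        assert pl.ndvi_annual([months]) == pytest.approx(pl.ndvi_annual([shuffled]))

    def test_empty_month_names_the_month(self):
        year = [self._month(0.5)] * 12
        year[4] = []
        with pytest.raises(ValueError, match="month 5"):
            pl.ndvi_annual([year])


class TestAggregateReserve:
    def test_plain_mean(self):
        assert pl.aggregate_reserve(GridLayer(np.array([[1.0, 2.0, 3.0]]))) == 2.0

    def test_nodata_excluded(self):
        layer = GridLayer(np.array([[1.0, 2.0, -9999.0]]), nodata=-9999.0)
        assert pl.aggregate_reserve(layer) == 1.5

    def test_single_cell_identity(self):
        assert pl.aggregate_reserve(GridLayer(np.array([[7.0]]))) == 7.0

    def test_constant_layer_any_mask(self):
        rng = np.random.default_rng(2)
        vals = np.full((6, 6), 3.25)
        vals[rng.random((6, 6)) < 0.4] = -9999.0
        layer = GridLayer(vals, nodata=-9999.0)
        assert pl.aggregate_reserve(layer) == 3.25

    def test_all_nodata_rejected(self):
        with pytest.raises(ValueError, match="valid"):
            pl.aggregate_reserve(GridLayer(np.full((2, 2), -9999.0), nodata=-9999.0))


class TestAsciiGridRoundTrip:
    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(4, 6))
        vals[0, 0] = -9999.0
        layer = GridLayer(vals, nodata=-9999.0, cellsize=0.25, xll=100.5, yll=30.25)
        path = tmp_path / "grid.asc"
        pl.write_ascii_grid(layer, path)
        back = pl.read_ascii_grid(path)
        assert np.array_equal(back.values, layer.values)
        assert back.cellsize == 0.25 and back.xll == 100.5 and back.yll == 30.25
        assert not back.mask[0, 0]

    def test_shape_mismatch_detected(self, tmp_path):
        p = tmp_path / "bad.asc"
        p.write_text("ncols 3\nnrows 2\ncellsize 1\nNODATA_value -9999\n1 2 3\n")
        with pytest.raises(ValueError, match="shape"):
            pl.read_ascii_grid(p)
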