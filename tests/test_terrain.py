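import numpy as np
import pytest

from microgrid import terrain
from microgrid.raster import RasterGrid


def grid(values, cell=1.0):
    values = np.asarray(values, dtype=float)
    return RasterGrid(values, cell, (0.0, values.shape[0] * cell))


def plane(n, a=0.0, b=0.0, c=100.0, cell=1.0):
    """z = a*x + b*y + c at cell centres (x east, y north)."""
    r = grid(np.zeros((n, n)), cell)
    x, y = np.meshgrid(r.x_centers(), r.y_centers())
    return r.like(a * x + b * y + c)


class TestResample:
    def test_constant(self):
        out = terrain.resample_bspline(grid(np.full((20, 20), 7.0)), 5.0)
        np.testing.assert_allclose(out.values, 7.0)
        assert out.shape == (4, 4)

    def test_plane_exact(self):
        src = plane(25, a=0.3, b=-0.2)
        out = terrain.resample_bspline(src, 5.0)
        x, y = np.meshgrid(out.x_centers(), out.y_centers())
        np.testing.assert_allclose(out.values, 0.3 * x - 0.2 * y + 100.0, atol=1e-9)

    def test_geometry_1m_to_5m(self):
        out = terrain.resample_bspline(grid(np.zeros((52, 37))), 5.0)
        assert out.shape == (10, 7)
        assert out.cell_size == 5.0

    def test_all_nodata(self):
        out = terrain.resample_bspline(grid(np.full((10, 10), np.nan)), 5.0)
        assert np.isnan(out.values).all()


class TestMosaic:
    def test_single_identity(self):
        r = plane(8, a=1.0)
        out = terrain.mosaic_blend([r], 25.0)
        np.testing.assert_allclose(out.values, r.values)

    def test_blend_midpoint_and_beyond(self):
        # two 5 m rasters overlapping in a 25 m (5-cell) strip
        cell = 5.0
        a = RasterGrid(np.full((4, 10), 100.0), cell, (0.0, 20.0))
        b = RasterGrid(np.full((4, 10), 200.0), cell, (25.0, 20.0))
        out = terrain.mosaic_blend([a, b], 25.0)
        # overlap columns are x in [25, 50) -> out columns 5..9
        col_mid = 7  # centre 37.5 m: 12.5 m inside a's footprint from its east edge
        assert out.values[0, col_mid] == pytest.approx(150.0)
        assert out.values[0, 2] == pytest.approx(100.0)  # a only
        assert out.values[0, 12] == pytest.approx(200.0)  # b only

    def test_disjoint_gap(self):
        a = RasterGrid(np.full((2, 2), 1.0), 1.0, (0.0, 2.0))
        b = RasterGrid(np.full((2, 2), 2.0), 1.0, (5.0, 2.0))
        out = terrain.mosaic_blend([a, b], 2.0)
        assert np.isnan(out.values[:, 3]).all()


class TestSlopeAspect:
    def test_flat(self):
        s, a = terrain.slope_aspect(grid(np.full((6, 6), 10.0)))
        np.testing.assert_allclose(s.values[1:-1, 1:-1], 0.0)
        assert np.isnan(a.values[1:-1, 1:-1]).all()

    def test_plane_gradient(self):
        # dz/dx = 1: surface rises east -> downslope aspect west (270 deg)
        s, a = terrain.slope_aspect(plane(7, a=1.0))
        assert s.values[3, 3] == pytest.approx(45.0)
        assert a.values[3, 3] == pytest.approx(270.0)
        # dz/dy = -1: falls north -> downslope aspect north (0/360)
        s2, a2 = terrain.slope_aspect(plane(7, b=-1.0))
        assert s2.values[3, 3] == pytest.approx(45.0)
        assert a2.values[3, 3] % 360 == pytest.approx(0.0, abs=1e-9)

    def test_cone_aspect_rotates(self):
        n = 21
        r = grid(np.zeros((n, n)))
        x, y = np.meshgrid(r.x_centers(), r.y_centers())
        cx, cy = x[n // 2, n // 2], y[n // 2, n // 2]
        cone = r.like(-np.hypot(x - cx, y - cy))  # apex up at centre
        _, a = terrain.slope_aspect(cone)
        # cells east of apex drain further east (aspect ~90), north ~0, etc.
        assert a.values[n // 2, n - 2] == pytest.approx(90.0, abs=1.0)
        assert a.values[1, n // 2] == pytest.approx(0.0, abs=1.0) or \
            a.values[1, n // 2] == pytest.approx(360.0, abs=1.0)
        assert a.values[n // 2, 1] == pytest.approx(270.0, abs=1.0)
        assert a.values[n - 2, n // 2] == pytest.approx(180.0, abs=1.0)

    def test_edges_nodata(self):
        s, _ = terrain.slope_aspect(plane(5, a=1.0))
        assert np.isnan(s.values[0]).all() and np.isnan(s.values[:, -1]).all()


class TestTPI:
    def test_constant_zero(self):
        out = terrain.tpi(grid(np.full((12, 12), 5.0)), 3.0)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    def test_bump_sign_and_brute_force(self):
        z = np.zeros((15, 15))
        z[7, 7] = 10.0
        r = grid(z)
        out = terrain.tpi(r, 2.5)
        # brute-force circular window mean at the bump
        yy, xx = np.mgrid[0:15, 0:15]
        for (i, j) in [(7, 7), (7, 8), (5, 5)]:
            inwin = (yy - i) ** 2 + (xx - j) ** 2 <= 2.5**2
            expect = z[i, j] - z[inwin].mean()
            assert out.values[i, j] == pytest.approx(expect, abs=1e-9)
        assert out.values[7, 7] > 0 and out.values[7, 8] < 0

    def test_large_radius_tends_to_global_anomaly(self):
        rng = np.random.default_rng(5)
        z = rng.normal(0, 1, (50, 50))
        r = grid(z)
        out = terrain.tpi(r, 500.0)  # window >> raster
        np.testing.assert_allclose(out.values, z - z.mean(), atol=1e-6)

    def test_standardize(self):
        rng = np.random.default_rng(6)
        t = grid(rng.normal(0, 3, (20, 20)))
        out = terrain.standardize_tpi(t)
        assert out.values.std() == pytest.approx(1.0)
        # scale invariance
        out2 = terrain.standardize_tpi(t.like(t.values * 7.3))
        np.testing.assert_allclose(out2.values, out.values, atol=1e-9)
        with pytest.raises(ValueError):
            terrain.standardize_tpi(grid(np.full((5, 5), 2.0)))


class TestFreeman:
    def test_outflow_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        dtm = grid(rng.normal(100, 5, (20, 20)))
        ff = terrain.freeman_accumulation(dtm)
        sums = ff.fractions.sum(axis=2)
        ok = ~ff.outlet & np.isfinite(dtm.values)
        np.testing.assert_allclose(sums[ok], 1.0, atol=1e-12)
        assert (ff.area[np.isfinite(dtm.values)] >= 1.0 - 1e-12).all()

    def test_bowl_pit_collects_everything(self):
        yy, xx = np.mgrid[0:15, 0:15]
        bowl = grid(((yy - 7) ** 2 + (xx - 7) ** 2) / 5.0)
        ff = terrain.freeman_accumulation(bowl, fill=False)
        assert ff.area[7, 7] == pytest.approx(15 * 15, rel=1e-9)

    def test_inclined_plane_row_areas(self):
        # plane falling east, interior rows: k-th column from the divide
        # accumulates k cells of area
        n = 14
        z = np.broadcast_to(-np.arange(n, dtype=float), (n, n)).copy() + 50
        ff = terrain.freeman_accumulation(grid(z), fill=False)
        mid = ff.area[n // 2]
        np.testing.assert_allclose(mid[:5], np.arange(1.0, 6.0), rtol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mass_conservation_50x50(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.normal(0, 1, (50, 50))
        from scipy.ndimage import gaussian_filter
        dtm = grid(100 + 20 * gaussian_filter(base, 3), cell=5.0)
        ff = terrain.freeman_accumulation(dtm)
        total = dtm.values.size * 25.0
        assert ff.area[ff.outlet].sum() == pytest.approx(total, rel=1e-6)


class TestWetness:
    def valley(self, n=20):
        # V-shaped valley draining along the middle column
        yy, xx = np.mgrid[0:n, 0:n]
        z = np.abs(xx - n // 2) * 2.0 + (n - yy) * 0.1
        return grid(z.astype(float), cell=1.0)

    def test_valley_axis_has_max_twi(self):
        v = self.valley()
        out = terrain.twi(v)
        interior = out.values[1:-1, 1:-1]
        col_of_max = np.nanargmax(interior, axis=1)
        assert (col_of_max == v.ncols // 2 - 1).all()

    def test_cell_size_doubling_shifts_by_ln2(self):
        # on a uniform plane the k-th column from the divide has a = k * cell
        # and the slope is scale-free, so doubling the cell size raises TWI
        # by exactly ln 2 at equal column index
        n = 16
        zf = np.broadcast_to(-np.arange(2 * n, dtype=float), (2 * n, 2 * n)).copy()
        zc = np.broadcast_to(-2.0 * np.arange(n, dtype=float), (n, n)).copy()
        fine = RasterGrid(zf, 1.0, (0.0, 2 * n))
        coarse = RasterGrid(zc, 2.0, (0.0, 2 * n))
        tf = terrain.twi(fine, terrain.freeman_accumulation(fine, fill=False))
        tc = terrain.twi(coarse, terrain.freeman_accumulation(coarse, fill=False))
        k = 6
        assert tc.values[7, k] - tf.values[8, k] == pytest.approx(np.log(2.0),
                                                                  abs=1e-9)

    def test_sagawi_at_least_twi(self, ):
        v = self.valley()
        t = terrain.twi(v)
        s = terrain.saga_wetness_index(v)
        m = np.isfinite(t.values) & np.isfinite(s.values)
        assert (s.values[m] >= t.values[m] - 1e-9).all()

    def test_sagawi_equals_twi_on_steep_slope(self):
        # uniform 30 degree slope: damping suppresses area modification
        n = 12
        z = np.broadcast_to(np.arange(n) * np.tan(np.radians(30.0)), (n, n)).copy()
        r = grid(z)
        t = terrain.twi(r)
        s = terrain.saga_wetness_index(r)
        m = np.isfinite(t.values)
        np.testing.assert_allclose(s.values[m], t.values[m], atol=1e-6)

    def test_sagawi_gain_largest_on_valley_floor(self):
        # flat floor bordered by steep walls: floor cells gain most
        n = 20
        yy, xx = np.mgrid[0:n, 0:n]
        z = np.maximum(np.abs(xx - n // 2) - 2, 0) * 3.0 + (n - yy) * 0.01
        r = grid(z.astype(float))
        gain = terrain.saga_wetness_index(r).values - terrain.twi(r).values
        interior = gain[1:-1, 1:-1]
        floor = interior[:, n // 2 - 3 : n // 2 + 1]
        walls = interior[:, : n // 2 - 4]
        assert np.nanmax(floor) == pytest.approx(np.nanmax(interior))
        assert np.nanmean(floor) > np.nanmean(walls)


class TestDAH:
    def mk(self, slope_deg, aspect_deg):
        s = grid(np.full((3, 3), float(slope_deg)))
        a = grid(np.full((3, 3), float(aspect_deg)))
        return terrain.dah(s, a).values[1, 1]

    def test_flat_zero(self):
        s = grid(np.zeros((3, 3)))
        a = grid(np.full((3, 3), np.nan))
        assert terrain.dah(s, a).values[1, 1] == 0.0

    def test_max_aspect_value(self):
        assert self.mk(45.0, 202.5) == pytest.approx(np.arctan(np.pi / 4), abs=1e-4)

    def test_antisymmetry(self):
        assert self.mk(45.0, 22.5) == pytest.approx(-np.arctan(np.pi / 4), abs=1e-4)
        # sign flips under reflection about the 112.5/292.5 axis
        for asp in (150.0, 250.0, 300.0):
            assert self.mk(30.0, asp) == pytest.approx(-self.mk(30.0, (225.0 - asp) % 360.0), abs=1e-9)

    def test_argmax_at_2025(self):
        aspects = np.arange(0.0, 360.0, 0.5)
        vals = [self.mk(30.0, a) for a in aspects]
        assert aspects[int(np.argmax(vals))] == 202.5

    def test_range_bounds(self):
        rng = np.random.default_rng(0)
        s = grid(rng.uniform(0, 89, (10, 10)))
        a = grid(rng.uniform(0, 360, (10, 10)))
        v = terrain.dah(s, a).values
        assert (v > -np.pi / 2).all() and (v < np.pi / 2).all()


class TestGaussianSmooth:
    def test_constant_unchanged(self):
        out = terrain.gaussian_smooth(grid(np.full((10, 10), 3.0)), 2.0)
        np.testing.assert_allclose(out.values, 3.0, atol=1e-9)

    def test_impulse_kernel(self):
        z = np.zeros((31, 31))
        z[15, 15] = 1.0
        out = terrain.gaussian_smooth(grid(z), 2.0)
        assert out.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert out.values[15, 15] == out.values.max()
        # isotropy
        assert out.values[15, 17] == pytest.approx(out.values[17, 15], abs=1e-12)

    def test_mean_preserved(self):
        rng = np.random.default_rng(8)
        r = grid(rng.normal(10, 2, (30, 30)), cell=5.0)
        out = terrain.gaussian_smooth(r, 10.0)
        assert out.values.mean() == pytest.approx(r.values.mean(), abs=1e-9)

    def test_nodata_ignored(self):
        z = np.full((10, 10), 4.0)
        z[0, 0] = np.nan
        out = terrain.gaussian_smooth(grid(z), 2.0)
        assert np.isnan(out.values[0, 0])
        np.testing.assert_allclose(out.values[np.isfinite(out.values)], 4.0, atol=1e-9)


class TestFillDepressions:
    def test_bowl_filled_to_drain(self):
        yy, xx = np.mgrid[0:9, 0:9]
        z = ((yy - 4) ** 2 + (xx - 4) ** 2) / 4.0 + 1.0
        z[4, 4] = -5.0  # pit
        out = terrain.fill_depressions(grid(z))
        # pit raised to at least the rim spill level
        assert out.values[4, 4] > z[4, 4]
        ff = terrain.freeman_accumulation(out, fill=False)
        # everything drains to the boundary
        assert ff.area[ff.outlet].sum() == pytest.approx(81.0, rel=1e-9)
        assert not ff.outlet[1:-1, 1:-1].any()
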