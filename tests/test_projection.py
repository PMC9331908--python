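"""Raster engine: ASCII grid I/O, pixel-level projection, latitude summaries."""

import numpy as np
import pytest

import craspetherm as ct
from craspetherm.errors import InvalidInputError, RasterFormatError
from craspetherm.rasters import NODATA_DEFAULT


def _write_constant_months(tmp_path, geometry, value, n=12):
    paths = []
    for m in range(n):
        p = tmp_path / f"t_{m + 1:02d}.asc"
        ct.write_ascii_grid(p, np.full((geometry.nrows, geometry.ncols), value), geometry)
        paths.append(p)
    return paths


class TestAsciiGridIO:
    def test_roundtrip_float32_and_nodata(self, tmp_path, small_geometry):
        rng = np.random.default_rng(0)
        arr = rng.uniform(-30, 30, (10, 10))
        arr[2, 3] = NODATA_DEFAULT
        p = tmp_path / "g.asc"
        ct.write_ascii_grid(p, arr, small_geometry)
        back, geom, nodata = ct.read_ascii_grid(p)
        np.testing.assert_array_equal(back.astype(np.float32), arr.astype(np.float32))
        assert geom.matches(small_geometry)
        assert nodata == NODATA_DEFAULT

    def test_missing_header(self, tmp_path):
        p = tmp_path / "bad.asc"
        p.write_text("ncols 3\n1 2 3\n")
        with pytest.raises(RasterFormatError):
            ct.read_ascii_grid(p)

    def test_shape_mismatch(self, tmp_path):
        p = tmp_path / "bad.asc"
        p.write_text(
            "ncols 3\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 1\n"
            "NODATA_value -9999\n1 2 3\n"
        )
        with pytest.raises(RasterFormatError):
            ct.read_ascii_grid(p)


class TestReadStack:
    def test_twelve_conforming_files(self, tmp_path, small_geometry):
        paths = _write_constant_months(tmp_path, small_geometry, 15.0)
        stack = ct.read_raster_stack(paths)
        assert stack.layers.shape == (12, 10, 10)
        assert np.all(stack.layers == 15.0)

    def test_wrong_count(self, tmp_path, small_geometry):
        paths = _write_constant_months(tmp_path, small_geometry, 15.0, n=11)
        with pytest.raises(RasterFormatError, match="12"):
            ct.read_raster_stack(paths)

    def test_geometry_mismatch_names_path(self, tmp_path, small_geometry):
        paths = _write_constant_months(tmp_path, small_geometry, 15.0)
        other = ct.GridGeometry(nrows=10, ncols=10, xll=-50.0, yll=-25.0, cellsize=2.0)
        ct.write_ascii_grid(paths[5], np.zeros((10, 10)), other)
        with pytest.raises(RasterFormatError, match="t_06"):
            ct.read_raster_stack(paths)

    def test_scale_divides_on_read(self, tmp_path, small_geometry):
        paths = _write_constant_months(tmp_path, small_geometry, 153.0)
        stack = ct.read_raster_stack(paths, scale=10.0)
        assert np.allclose(stack.layers, 15.3)

    def test_unreadable_path(self, tmp_path, small_geometry):
        paths = _write_constant_months(tmp_path, small_geometry, 15.0)
        paths[3] = tmp_path / "missing.asc"
        with pytest.raises(RasterFormatError, match="missing.asc"):
            ct.read_raster_stack(paths)


class TestProjectTHS:
    def test_constant_stack_at_optimum(self, canonical_fit, make_constant_stack):
        maps = ct.project_ths(canonical_fit, make_constant_stack(canonical_fit.t_opt))
        assert np.all(maps.layers == pytest.approx(1.0))

    def test_constant_stack_beyond_ct_max(self, canonical_fit, make_constant_stack):
        maps = ct.project_ths(canonical_fit, make_constant_stack(canonical_fit.ct_max + 5))
        assert np.all(maps.layers == 0.0)

    def test_matches_per_pixel_scalar_loop(self, canonical_fit, small_geometry):
        """Brute-force per-pixel oracle on a 10x10 grid."""
        rng = np.random.default_rng(5)
        layers = rng.uniform(-10, 45, (12, 10, 10))
        layers[:, 0, 0] = NODATA_DEFAULT
        stack = ct.TemperatureRasterStack(layers, small_geometry)
        maps = ct.project_ths(canonical_fit, stack)
        for m in range(12):
            for i in range(10):
                for j in range(10):
                    if layers[m, i, j] == NODATA_DEFAULT:
                        assert maps.layers[m, i, j] == np.float32(NODATA_DEFAULT)
                    else:
                        expected = ct.ths_at(canonical_fit, layers[m, i, j])
                        assert maps.layers[m, i, j] == pytest.approx(expected, abs=1e-6)

    def test_nodata_mask_preserved(self, canonical_fit, small_geometry):
        layers = np.full((12, 10, 10), 20.0)
        layers[:, 3, :] = NODATA_DEFAULT
        stack = ct.TemperatureRasterStack(layers, small_geometry)
        maps = ct.project_ths(canonical_fit, stack)
        np.testing.assert_array_equal(maps.mask, stack.mask)

    def test_projection_commutes_with_cropping(self, canonical_fit, small_geometry):
        rng = np.random.default_rng(8)
        layers = rng.uniform(0, 40, (12, 10, 10))
        stack = ct.TemperatureRasterStack(layers, small_geometry)
        rows, cols = slice(2, 7), slice(1, 9)
        a = ct.project_ths(canonical_fit, stack).crop(rows, cols)
        b = ct.project_ths(canonical_fit, stack.crop(rows, cols))
        np.testing.assert_array_equal(a.layers, b.layers)
        assert a.geometry.matches(b.geometry)

    def test_warming_monotonicity(self, canonical_fit, small_geometry):
        """+delta strictly raises THS below t_opt - delta, lowers it above t_opt."""
        rng = np.random.default_rng(3)
        layers = rng.uniform(5, 34, (12, 10, 10))
        stack = ct.TemperatureRasterStack(layers, small_geometry)
        delta = 2.0
        warmed = stack.with_offset(delta)
        a = ct.project_ths(canonical_fit, stack).layers.astype(float)
        b = ct.project_ths(canonical_fit, warmed).layers.astype(float)
        below = layers < canonical_fit.t_opt - delta
        above = (layers > canonical_fit.t_opt) & (layers < canonical_fit.ct_max)
        assert np.all(b[below] > a[below])
        assert np.all(b[above] < a[above])


class TestLatBandSummary:
    def test_uniform_half(self, canonical_fit, small_geometry):
        layers = np.full((12, 10, 10), 0.5, dtype=np.float32)
        maps = ct.THSMapSet(layers, small_geometry)
        summary = ct.monthly_latband_summary(maps, band_width=10.0)
        occupied = summary.table[summary.table.n_pixels > 0]
        assert np.allclose(occupied.mean_ths, 0.5)
        assert np.allclose(occupied.optimal_fraction, 0.0)
        # every (band, month) combination appears exactly once
        assert len(summary.table) == 18 * 12
        assert not summary.table.duplicated(["band_lower", "month"]).any()

    def test_uniform_optimal(self, small_geometry):
        layers = np.full((12, 10, 10), 0.7, dtype=np.float32)
        maps = ct.THSMapSet(layers, small_geometry)
        summary = ct.monthly_latband_summary(maps, band_width=10.0)
        occupied = summary.table[summary.table.n_pixels > 0]
        assert np.allclose(occupied.optimal_fraction, 1.0)

    def test_empty_bands_kept_with_marker(self, small_geometry):
        layers = np.full((12, 10, 10), 0.5, dtype=np.float32)
        maps = ct.THSMapSet(layers, small_geometry)
        summary = ct.monthly_latband_summary(maps, band_width=10.0)
        # grid spans latitudes [-25, 25]; polar bands have no pixels
        polar = summary.table[summary.table.band_lower == -90.0]
        assert (polar.n_pixels == 0).all()
        assert polar.mean_ths.isna().all()

    def test_band_width_must_divide_180(self, small_geometry):
        layers = np.full((12, 10, 10), 0.5, dtype=np.float32)
        with pytest.raises(InvalidInputError):
            ct.monthly_latband_summary(ct.THSMapSet(layers, small_geometry), band_width=7.0)


class TestOptimalMonths:
    def _uniform_maps(self, value, geometry):
        return ct.THSMapSet(np.full((12, 10, 10), value, dtype=np.float32), geometry)

    def test_all_optimal(self, small_geometry):
        summary = ct.monthly_latband_summary(self._uniform_maps(1.0, small_geometry))
        assert ct.optimal_months(summary, (-20.0, -10.0)) == list(range(1, 13))

    def test_none_optimal(self, small_geometry):
        summary = ct.monthly_latband_summary(self._uniform_maps(0.0, small_geometry))
        assert ct.optimal_months(summary, (-20.0, -10.0)) == []

    def test_matches_manual_row_filter(self, canonical_fit, small_geometry):
        rng = np.random.default_rng(5)
        layers = rng.uniform(-10, 45, (12, 10, 10))
        stack = ct.TemperatureRasterStack(layers, small_geometry)
        summary = ct.monthly_latband_summary(ct.project_ths(canonical_fit, stack))
        band = (0.0, 10.0)
        rows = summary.band(*band)
        manual = sorted(rows[rows.optimal_fraction > 0.5].month.astype(int))
        assert ct.optimal_months(summary, band, 0.5) == manual

    def test_unknown_band(self, small_geometry):
        summary = ct.monthly_latband_summary(self._uniform_maps(0.5, small_geometry))
        with pytest.raises(InvalidInputError):
            ct.optimal_months(summary, (12.5, 17.5))


def test_mapset_write_read_roundtrip(tmp_path, canonical_fit, small_geometry):
    rng = np.random.default_rng(1)
    layers = rng.uniform(0, 40, (12, 10, 10))
    layers[:, 4, 4] = NODATA_DEFAULT
    maps = ct.project_ths(canonical_fit, ct.TemperatureRasterStack(layers, small_geometry))
    paths = ct.write_stack(maps, tmp_path, "ths")
    assert len(paths) == 12
    arrays = [ct.read_ascii_grid(p)[0] for p in paths]
    np.testing.assert_array_equal(
        np.stack(arrays).astype(np.float32), maps.layers
    )
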