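import numpy as np
import pytest
from shapely.geometry import box

from uavyield.errors import (
    CRSMismatchError,
    PlotClipError,
    PlotGeometryError,
    RasterFormatError,
)
from uavyield.geo import (
    Affine,
    BandStack,
    MULTISPECTRAL_BANDS,
    PlotGeometry,
    clip_to_plot,
    read_elevation,
    read_plots,
    read_raster,
    write_plots,
    write_raster,
)


def _stack(shape=(20, 20), nbands=5, nodata=0.0, seed=0):
    rng = np.random.default_rng(seed)
    data = rng.integers(1, 1000, size=(nbands, *shape)).astype(float)
    names = MULTISPECTRAL_BANDS[:nbands]
    return BandStack(
        dict(zip(names, data)),
        Affine(1.0, 0.0, 0.0, 0.0, -1.0, float(shape[0])),
        "EPSG:32650",
        nodata=nodata,
    )


class TestRasterRoundTrip:
    def test_integer_raster_round_trips_bit_exactly(self, tmp_path):
        stack = _stack()
        path = tmp_path / "ms.tif"
        write_raster(path, stack, dtype=np.uint16)
        back = read_raster(path, MULTISPECTRAL_BANDS)
        for b in MULTISPECTRAL_BANDS:
            np.testing.assert_array_equal(back.bands[b], stack.bands[b])
        assert back.transform == stack.transform
        assert back.crs == stack.crs
        assert back.nodata == stack.nodata

    def test_single_band_elevation_preserves_shape(self, tmp_path):
        from uavyield.geo import ElevationRaster, write_elevation

        dsm = ElevationRaster(
            np.full((7, 9), 80.5), "DSM", Affine(1, 0, 0, 0, -1, 7.0), "EPSG:32650"
        )
        write_elevation(tmp_path / "dsm.tif", dsm)
        back = read_elevation(tmp_path / "dsm.tif", "DSM")
        assert back.shape == (7, 9)
        assert back.kind == "DSM"
        np.testing.assert_array_equal(back.values, dsm.values)

    def test_band_count_mismatch_raises(self, tmp_path):
        stack = _stack(nbands=3)
        path = tmp_path / "three.tif"
        write_raster(path, stack)
        with pytest.raises(RasterFormatError, match="3 bands.*5"):
            read_raster(path, MULTISPECTRAL_BANDS)

    def test_missing_file_raises(self):
        with pytest.raises(RasterFormatError, match="not found"):
            read_raster("/nonexistent/x.tif", MULTISPECTRAL_BANDS)

    def test_nodata_pixels_masked_on_read(self, tmp_path):
        stack = _stack()
        stack.bands["blue"][2, 3] = 0.0  # nodata sentinel in one band
        write_raster(tmp_path / "m.tif", stack, dtype=np.uint16)
        back = read_raster(tmp_path / "m.tif", MULTISPECTRAL_BANDS)
        assert not back.mask[2, 3]
        assert back.mask.sum() == 20 * 20 - 1


class TestClipToPlot:
    def test_exact_central_block_keeps_pixel_count(self):
        stack = _stack(shape=(100, 100))
        plot = PlotGeometry("P1", box(45.0, 45.0, 55.0, 55.0))
        clipped = clip_to_plot(stack, plot)
        assert int(clipped.mask.sum()) == 100
        assert clipped.shape == (10, 10)

    def test_edge_overlap_masks_outside_extent(self):
        stack = _stack(shape=(10, 10))
        plot = PlotGeometry("edge", box(-5.0, 2.0, 3.0, 8.0))
        clipped = clip_to_plot(stack, plot)
        # only the 3 in-raster columns of the 8-wide polygon survive
        assert int(clipped.mask.sum()) == 3 * 6

    def test_disjoint_polygon_names_plot(self):
        stack = _stack(shape=(10, 10))
        plot = PlotGeometry("faraway", box(500.0, 500.0, 510.0, 510.0))
        with pytest.raises(PlotClipError, match="faraway"):
            clip_to_plot(stack, plot)

    def test_clipped_transform_georeferences_same_pixels(self):
        stack = _stack(shape=(50, 50))
        plot = PlotGeometry("P1", box(10.0, 10.0, 20.0, 20.0))
        clipped = clip_to_plot(stack, plot)
        # the first valid pixel's center must be identical through both transforms
        r, c = np.argwhere(clipped.mask)[0]
        x, y = clipped.transform.xy(r, c)
        assert 10 < x < 20 and 10 < y < 20

    def test_crs_mismatch_is_an_error_not_a_reprojection(self):
        stack = _stack()
        plot = PlotGeometry("P1", box(5, 5, 10, 10), crs="EPSG:4326")
        with pytest.raises(CRSMismatchError):
            clip_to_plot(stack, plot)

    def test_clip_mask_commutes_with_containment(self):
        """Pixel sets from clipping equal direct pixel-center containment."""
        import shapely

        stack = _stack(shape=(30, 30), seed=3)
        stack.mask[::3, ::4] = False
        plot = PlotGeometry("P1", box(4.3, 6.1, 17.8, 21.2))
        clipped = clip_to_plot(stack, plot)
        rows, cols = np.meshgrid(np.arange(30), np.arange(30), indexing="ij")
        xs, ys = stack.transform.xy(rows, cols)
        inside = shapely.contains_xy(plot.polygon, xs.ravel(), ys.ravel()).reshape(30, 30)
        assert int(clipped.mask.sum()) == int((inside & stack.mask).sum())


class TestPlotCollections:
    def _write(self, tmp_path, n=5, ids=None):
        plots = [
            PlotGeometry(ids[k] if ids else f"P{k:03d}", box(k * 10, 0, k * 10 + 8, 8))
            for k in range(n)
        ]
        path = tmp_path / "plots.geojson"
        write_plots(path, plots, "EPSG:32650")
        return path

    def test_round_trip_ordered_by_plot_id(self, tmp_path):
        path = self._write(tmp_path, n=132)
        plots = read_plots(path)
        assert len(plots) == 132
        assert [p.plot_id for p in plots] == sorted(p.plot_id for p in plots)
        assert plots[0].crs == "EPSG:32650"

    def test_duplicate_plot_ids_listed(self, tmp_path):
        path = self._write(tmp_path, n=4, ids=["A", "B", "A", "C"])
        with pytest.raises(PlotGeometryError, match="duplicate.*A"):
            read_plots(path)

    def test_empty_collection_warns(self, tmp_path):
        path = tmp_path / "empty.geojson"
        path.write_text('{"type": "FeatureCollection", "features": []}')
        with pytest.warns(UserWarning, match="empty"):
            assert read_plots(path) == []

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(PlotGeometryError):
            PlotGeometry("bad", box(0, 0, 0, 0))


def test_nonoverlapping_plots_cover_at_most_raster(small_scenario):
    total = 0
    rgb = small_scenario.stage_rasters["R5"].rgb
    for plot in small_scenario.plots:
        total += int(clip_to_plot(rgb, plot).mask.sum())
    assert total <= rgb.shape[0] * rgb.shape[1]
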