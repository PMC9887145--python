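import numpy as np
import pytest

from uavyield.canopy import (
    DEFAULT_CIVE_INTERVAL,
    VEGETATION_INDICES,
    aggregate_plot_features,
    compute_canopy_mask,
    compute_cc,
    compute_chm,
    compute_cive,
    compute_vegetation_indices,
    plot_canopy_height,
    register_index,
)
from uavyield.errors import FeatureError, PlotClipError
from uavyield.geo import Affine, BandStack, ElevationRaster

T = Affine(1.0, 0.0, 0.0, 0.0, -1.0, 4.0)


def refl_stack(blue=0.05, green=0.1, red=0.1, rededge=0.3, nir=0.5, shape=(4, 4)):
    bands = {
        "blue": np.full(shape, blue),
        "green": np.full(shape, green),
        "red": np.full(shape, red),
        "rededge": np.full(shape, rededge),
        "nir": np.full(shape, nir),
    }
    return BandStack(bands, T, is_reflectance=True)


class TestVegetationIndices:
    def test_worked_example_nir05_red01(self):
        vis = compute_vegetation_indices(refl_stack(red=0.1, nir=0.5))
        assert vis.maps["NDVI"][0, 0] == pytest.approx(0.4 / 0.6, abs=1e-4)
        assert vis.maps["RVI"][0, 0] == pytest.approx(5.0)
        assert vis.maps["EVI2"][0, 0] == pytest.approx(2.5 * 0.4 / (0.5 + 0.24 + 1.0), abs=1e-4)

    def test_nir_equals_red_symmetry(self):
        vis = compute_vegetation_indices(refl_stack(red=0.2, nir=0.2))
        assert vis.maps["NDVI"][0, 0] == 0.0
        expected = (0.12 * 0.2 - 0.2) / (0.12 * 0.2 + 0.2)
        assert vis.maps["WDRVI"][0, 0] == pytest.approx(expected)
        assert vis.maps["WDRVI"][0, 0] == pytest.approx(-0.785714, abs=1e-6)

    def test_nir_equals_green_identities(self):
        vis = compute_vegetation_indices(refl_stack(green=0.3, nir=0.3))
        assert vis.maps["GNDVI"][0, 0] == 0.0
        assert vis.maps["GCI"][0, 0] == pytest.approx(0.0)

    def test_osavi_as_published_vs_canonical(self):
        stack = refl_stack(red=0.1, nir=0.5)
        printed = compute_vegetation_indices(stack).maps["OSAVI"][0, 0]
        canonical = compute_vegetation_indices(stack, osavi_canonical=True).maps["OSAVI"][0, 0]
        assert printed == pytest.approx(0.4 / (0.4 + 0.16))
        assert canonical == pytest.approx(0.4 / (0.6 + 0.16))

    def test_uniform_stack_indices_are_constant_scalars(self):
        stack = refl_stack(blue=0.04, green=0.11, red=0.08, rededge=0.25, nir=0.47)
        vis = compute_vegetation_indices(stack)
        for name, vals in vis.maps.items():
            assert np.ptp(vals) == 0, name

    def test_all_thirteen_published_indices_present(self):
        names = {
            "NDVI", "RVI", "GRVI", "OSAVI", "NDRE", "MCARI", "TCARI",
            "GNDVI", "WDRVI", "GCI", "RECI", "EVI2", "NDREI",
        }
        assert names <= set(VEGETATION_INDICES)

    def test_registry_accepts_additional_index(self):
        register_index("EXG_TEST", lambda B, G, R, RE, NIR: 2 * G - R - B)
        try:
            vis = compute_vegetation_indices(refl_stack())
            assert "EXG_TEST" in vis.maps
        finally:
            VEGETATION_INDICES.pop("EXG_TEST")

    def test_zero_denominator_counted_and_nan(self):
        stack = refl_stack()
        stack.bands["red"][0, 0] = 0.0
        stack.bands["nir"][0, 0] = 0.0
        vis = compute_vegetation_indices(stack)
        assert np.isnan(vis.maps["NDVI"][0, 0])
        assert vis.zero_denominator_counts["NDVI"] == 1

    def test_dn_stack_rejected(self):
        stack = refl_stack()
        stack.is_reflectance = False
        with pytest.raises(FeatureError, match="reflectance"):
            compute_vegetation_indices(stack)


class TestCive:
    @pytest.mark.parametrize(
        "rgb,expected",
        [
            ((100, 150, 80), -27.963),
            ((128, 128, 128), 20.707),
            ((0, 0, 0), 18.787),
        ],
    )
    def test_hand_values(self, rgb, expected):
        r, g, b = rgb
        bands = {"R": np.full((2, 2), float(r)), "G": np.full((2, 2), float(g)), "B": np.full((2, 2), float(b))}
        assert compute_cive(bands)[0, 0] == pytest.approx(expected, abs=1e-9)

    def test_missing_band_rejected(self):
        with pytest.raises(FeatureError):
            compute_cive({"R": np.zeros((2, 2)), "G": np.zeros((2, 2))})


class TestCanopyMaskAndCC:
    def test_interval_inclusive_on_both_ends(self):
        cive = np.array([[-28.0, 5.0], [-28.001, 5.001]])
        mask = compute_canopy_mask(cive, DEFAULT_CIVE_INTERVAL).mask
        assert mask.tolist() == [[True, True], [False, False]]

    def test_hand_cive_values_classified(self):
        cive = np.array([[-27.963, 20.707]])
        mask = compute_canopy_mask(cive).mask
        assert mask.tolist() == [[True, False]]

    def test_inverted_interval_rejected(self):
        with pytest.raises(FeatureError):
            compute_canopy_mask(np.zeros((2, 2)), (5.0, -28.0))

    @pytest.mark.parametrize("n_canopy,expected", [(40, 0.40), (100, 1.0), (0, 0.0)])
    def test_cc_is_pixel_fraction(self, n_canopy, expected):
        cive = np.full(100, 50.0)
        cive[:n_canopy] = 0.0  # inside [-28, 5]
        canopy = compute_canopy_mask(cive.reshape(10, 10))
        assert compute_cc(canopy) == pytest.approx(expected)

    def test_cc_monotone_under_mask_union(self):
        rng = np.random.default_rng(0)
        a = rng.random((10, 10)) < 0.3
        b = rng.random((10, 10)) < 0.3
        valid = np.ones((10, 10), bool)
        from uavyield.canopy import CanopyMask

        cc = lambda m: compute_cc(CanopyMask(m, np.zeros((10, 10)), (0, 1), valid))
        assert cc(a | b) >= max(cc(a), cc(b))


class TestChm:
    def _elev(self, values, kind):
        return ElevationRaster(np.asarray(values, float), kind, T)

    def test_subtraction(self):
        chm = compute_chm(self._elev([[80.5]], "DSM"), self._elev([[75.0]], "DEM"))
        assert chm.values[0, 0] == pytest.approx(5.5)
        assert chm.kind == "CHM"

    def test_negative_clamped_and_counted(self):
        chm = compute_chm(self._elev([[74.9, 76.0]], "DSM"), self._elev([[75.0, 75.0]], "DEM"))
        assert chm.values[0, 0] == 0.0
        assert chm.n_clamped == 1

    def test_nodata_propagates(self):
        dem = self._elev([[75.0, 75.0]], "DEM")
        dem.mask = np.array([[False, True]])
        chm = compute_chm(self._elev([[80.0, 80.0]], "DSM"), dem)
        assert not chm.mask[0, 0] and chm.mask[0, 1]

    def test_grid_mismatch_rejected(self):
        other = ElevationRaster(np.zeros((1, 2)), "DEM", Affine(2, 0, 0, 0, -2, 2.0))
        with pytest.raises(FeatureError, match="co-registered"):
            compute_chm(self._elev([[80.0, 80.0]], "DSM"), other)

    def test_vertical_datum_shift_invariance(self):
        rng = np.random.default_rng(1)
        dsm = rng.uniform(75, 80, (6, 6))
        dem = rng.uniform(74, 76, (6, 6))
        base = compute_chm(self._elev(dsm, "DSM"), self._elev(dem, "DEM"))
        shifted = compute_chm(self._elev(dsm + 13.0, "DSM"), self._elev(dem + 13.0, "DEM"))
        np.testing.assert_allclose(base.values, shifted.values, atol=1e-9)


class TestPlotHeight:
    def _chm(self, values):
        return ElevationRaster(np.asarray(values, float), "CHM", T)

    def _canopy(self, mask):
        from uavyield.canopy import CanopyMask

        mask = np.asarray(mask, bool)
        return CanopyMask(mask, np.zeros(mask.shape), (0, 1), np.ones(mask.shape, bool))

    def test_constant_canopy_height(self):
        assert plot_canopy_height(self._chm([[2.0, 2.0]]), self._canopy([[True, True]])) == 2.0

    def test_mean_over_canopy_pixels_only(self):
        chm = self._chm([[1.0, 2.0, 3.0, 99.0]])
        canopy = self._canopy([[True, True, True, False]])
        assert plot_canopy_height(chm, canopy) == pytest.approx(2.0)

    def test_empty_canopy_falls_back_with_warning(self):
        chm = self._chm([[0.4, 0.4]])
        with pytest.warns(UserWarning, match="all-pixel"):
            assert plot_canopy_height(chm, self._canopy([[False, False]])) == pytest.approx(0.4)


class TestAggregation:
    def test_constant_and_mixed_maps(self):
        valid = np.ones((2, 2), bool)
        maps = {"NDVI": np.full((2, 2), 0.8), "X": np.array([[0.2, 0.2], [0.6, 0.6]])}
        agg = aggregate_plot_features(maps, valid)
        assert agg["NDVI"] == pytest.approx(0.8)
        assert agg["X"] == pytest.approx(0.4)

    def test_all_invalid_names_plot(self):
        with pytest.raises(PlotClipError, match="P007"):
            aggregate_plot_features({"NDVI": np.ones((2, 2))}, np.zeros((2, 2), bool), "P007")
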