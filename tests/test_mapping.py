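import numpy as np
import pytest

from xanthomap.errors import DataError
from xanthomap.mapping import (
    PigmentMap,
    find_center,
    line_cross_section,
    map_pixelwise,
    radial_profile,
    region_ratios,
    segment_regions,
    zscan_profile,
)
from xanthomap.spectra import SpectralMap
from xanthomap.synthetic import RetinaGeometry, synth_retina_map, synth_spectrum, synth_zscan


def _uniform_map(basis, f_zea, n=6, laser=514, total=1.0):
    spec, _ = synth_spectrum(basis, f_zea, laser, total_concentration=total)
    cube = np.tile(spec.intensity, (n, n, 1))
    return SpectralMap("XY", basis.wavenumbers, cube, (10.0, 10.0), laser)


def _truth_pigment_map(geometry, pixel_um=10.0):
    """PigmentMap assembled directly from generator truth (no fitting)."""
    n = int(round(geometry.map_extent_mm * 1000 / pixel_um))
    coords = ((np.arange(n) + 0.5) * pixel_um - geometry.map_extent_mm * 500) / 1000.0
    xx, yy = np.meshgrid(coords, coords)
    r = np.hypot(xx, yy)
    total = geometry.truth_total(r)
    f = geometry.truth_f_zea(r)
    images = {
        "lut": total * (1 - f),
        "zea": total * f,
        "total": total,
        "nu1_area": total,
        "fwhm": np.full_like(total, 14.0),
        "fraction_zea": f,
        "raw_fraction_zea": f,
    }
    return PigmentMap("XY", (pixel_um, pixel_um), images,
                      np.zeros((n, n), bool), 514)


@pytest.fixture(scope="module")
def scaled_map(basis, small_geometry):
    smap, truth = synth_retina_map(basis, small_geometry, 514, seed=0, noise_sd=0.0)
    pmap = map_pixelwise(smap, {"basis": basis})
    return smap, truth, pmap


class TestMapPixelwise:
    def test_uniform_map_constant_fraction(self, basis):
        smap = _uniform_map(basis, 0.5)
        pmap = map_pixelwise(smap, {"basis": basis})
        frac = pmap.images["fraction_zea"]
        assert np.all(np.abs(frac - 0.5) < 0.01)

    def test_mass_consistency(self, scaled_map):
        _, _, pmap = scaled_map
        total = pmap.images["lut"] + pmap.images["zea"]
        np.testing.assert_allclose(total, pmap.images["total"], rtol=1e-9)

    def test_fwhm_constant_on_pure_map(self, basis):
        smap = _uniform_map(basis, 0.0, laser=488)
        pmap = map_pixelwise(smap, {"basis": basis})
        fwhm = pmap.images["fwhm"]
        assert np.ptp(fwhm) < 1e-9
        assert fwhm[0, 0] == pytest.approx(14.0, abs=0.1)

    def test_failed_pixels_masked_and_excluded(self, basis):
        smap = _uniform_map(basis, 0.5, n=6)
        smap.intensity[2, 3] = 0.0  # flat spectrum: nu1 cannot be located
        pmap = map_pixelwise(smap, {"basis": basis})
        assert pmap.failed[2, 3]
        assert pmap.failed.sum() == 1
        assert np.isnan(pmap.images["total"][2, 3])
        profile = radial_profile(pmap, (30.0, 30.0), 100.0)
        assert profile.n.sum() == 35  # 36 pixels minus the masked one

    def test_failure_threshold_enforced(self, basis):
        smap = _uniform_map(basis, 0.5, n=4)
        smap.intensity[:2] = 0.0  # half the map unusable
        from xanthomap.errors import NumericalError

        with pytest.raises(NumericalError):
            map_pixelwise(smap, {"basis": basis}, failure_threshold=0.2)


class TestFindCenter:
    def test_single_bright_pixel(self, basis):
        pmap = _truth_pigment_map(RetinaGeometry(), pixel_um=100.0)
        img = np.zeros_like(pmap.images["total"])
        img[4, 7] = 1.0
        pmap.images["total"] = img
        x, y = find_center(pmap)
        assert x == pytest.approx((7 + 0.5) * 100.0)
        assert y == pytest.approx((4 + 0.5) * 100.0)

    def test_centroid_on_truth_map(self):
        geom = RetinaGeometry(map_extent_mm=1.5, pixel_size_um=10.0)
        pmap = _truth_pigment_map(geom)
        x, y = find_center(pmap)
        assert x == pytest.approx(750.0, abs=10.0)
        assert y == pytest.approx(750.0, abs=10.0)

    def test_constant_image_rejected(self, basis):
        pmap = _truth_pigment_map(RetinaGeometry(), pixel_um=100.0)
        pmap.images["total"] = np.ones_like(pmap.images["total"])
        with pytest.raises(DataError):
            find_center(pmap)


class TestRadialProfile:
    def test_uniform_map_flat_profile(self, basis):
        smap = _uniform_map(basis, 0.4, n=8)
        pmap = map_pixelwise(smap, {"basis": basis})
        prof = radial_profile(pmap, (40.0, 40.0), 10.0)
        means = prof.mean["total"][prof.n > 0]
        assert np.nanmax(np.abs(means - np.nanmean(means))) < 0.01 * np.nanmean(means)

    def test_truth_ratio_plateaus_recovered(self):
        """Zea:Lut ratio profile: ~2 in the center, ~0.3 beyond the parafovea."""
        geom = RetinaGeometry(map_extent_mm=3.0, pixel_size_um=20.0)
        pmap = _truth_pigment_map(geom, pixel_um=20.0)
        prof = radial_profile(pmap, (1500.0, 1500.0), 20.0)
        inner = prof.radius_um < 100.0
        assert np.nanmean(prof.ratio[inner]) == pytest.approx(2.0, abs=0.1)
        outer = (prof.radius_um > 1100.0) & (prof.radius_um < 1400.0)
        assert np.nanmean(prof.ratio[outer]) == pytest.approx(0.3, abs=0.05)

    def test_center_outside_map_rejected(self, basis):
        smap = _uniform_map(basis, 0.4)
        pmap = map_pixelwise(smap, {"basis": basis})
        with pytest.raises(DataError):
            radial_profile(pmap, (1e6, 1e6), 10.0)


class TestSegmentation:
    def test_fixed_mode_radii_and_partition(self):
        pmap = _truth_pigment_map(RetinaGeometry(map_extent_mm=3.0), pixel_um=50.0)
        seg = segment_regions(pmap, (1500.0, 1500.0), mode="fixed")
        assert seg.boundary_radii_um[0] == pytest.approx(175.0)
        assert seg.boundary_radii_um == (175.0, 500.0, 1000.0)
        # labels partition the map
        assert set(np.unique(seg.labels)) <= {0, 1, 2, 3}
        assert seg.labels.size == pmap.images["total"].size

    def test_data_driven_recovers_foveola_diameter(self):
        """Foveola diameter from the concentration-profile shoulders: 0.35 +- 0.05 mm."""
        geom = RetinaGeometry(map_extent_mm=1.5, pixel_size_um=10.0)
        pmap = _truth_pigment_map(geom)
        seg = segment_regions(pmap, (750.0, 750.0), mode="data_driven")
        assert 2 * seg.boundary_radii_um[0] / 1000.0 == pytest.approx(0.35, abs=0.05)

    def test_data_driven_flat_profile_rejected(self, basis):
        smap = _uniform_map(basis, 0.4, n=8)
        pmap = map_pixelwise(smap, {"basis": basis})
        with pytest.raises(DataError):
            segment_regions(pmap, (40.0, 40.0), mode="data_driven")


class TestRegionRatios:
    def test_scaled_map_recovers_truth_ratios(self, scaled_map, small_geometry, basis):
        _, _, pmap = scaled_map
        d1 = small_geometry.foveola_diameter_mm
        d2 = small_geometry.fovea_diameter_mm
        d3 = small_geometry.parafovea_diameter_mm
        seg = segment_regions(pmap, (400.0, 400.0), mode="fixed",
                              fixed_diameters_mm=(d1, d2, d3))
        reg = region_ratios(pmap, seg)
        assert reg["foveola"]["ratio"] == pytest.approx(2.0, rel=0.1)
        assert reg["outside"]["ratio"] == pytest.approx(0.3, rel=0.1)
        assert reg["foveola"]["mean_total"] / reg["outside"]["mean_total"] == pytest.approx(
            100.0, rel=0.1
        )

    def test_rotation_robustness(self, scaled_map, small_geometry, basis):
        """Rotating the map 90 degrees changes region ratios by < 1%."""
        smap, _, pmap = scaled_map
        rotated = SpectralMap(
            "XY", smap.wavenumbers, np.rot90(smap.intensity, axes=(0, 1)).copy(),
            smap.pixel_size_um, smap.laser_nm,
        )
        pmap_rot = map_pixelwise(rotated, {"basis": basis})
        dia = (small_geometry.foveola_diameter_mm, small_geometry.fovea_diameter_mm,
               small_geometry.parafovea_diameter_mm)
        reg = region_ratios(pmap, segment_regions(pmap, (400.0, 400.0), "fixed", dia))
        reg_rot = region_ratios(
            pmap_rot, segment_regions(pmap_rot, (400.0, 400.0), "fixed", dia)
        )
        for name in ("foveola", "fovea", "parafovea", "outside"):
            assert reg_rot[name]["ratio"] == pytest.approx(reg[name]["ratio"], rel=0.01)

    def test_empty_region_reported_missing(self, basis):
        smap = _uniform_map(basis, 0.5, n=4)  # 40 x 40 um map
        pmap = map_pixelwise(smap, {"basis": basis})
        seg = segment_regions(pmap, (20.0, 20.0), mode="fixed",
                              fixed_diameters_mm=(1.0, 2.0, 3.0))
        reg = region_ratios(pmap, seg)
        assert reg["foveola"] is not None
        assert reg["outside"] is None


class TestCrossSection:
    def test_uniform_map_constant_profile(self, basis):
        smap = _uniform_map(basis, 0.4, n=8)
        pmap = map_pixelwise(smap, {"basis": basis})
        prof = line_cross_section(pmap, (5.0, 40.0), (75.0, 40.0), width_px=3)
        vals = prof["total"]
        assert np.nanmax(np.abs(vals - np.nanmean(vals))) < 1e-6 * np.nanmean(vals)

    def test_through_center_peaks_at_center(self, scaled_map):
        _, _, pmap = scaled_map
        prof = line_cross_section(pmap, (20.0, 400.0), (780.0, 400.0), width_px=1)
        i = np.nanargmax(prof["total"])
        assert abs(prof["distance_um"][i] - 380.0) <= 40.0  # within one pixel

    def test_zero_length_rejected(self, scaled_map):
        _, _, pmap = scaled_map
        with pytest.raises(DataError):
            line_cross_section(pmap, (100.0, 100.0), (100.0, 100.0))


class TestZScan:
    def test_layer_recovery(self, basis):
        smap, truth = synth_zscan(
            basis, layer_center_um=20.0, layer_fwhm_um=10.0,
            f_zea_profile=0.4, laser_nm=514, seed=0, width_um=5.0,
        )
        prof = zscan_profile(smap, {"basis": basis})
        assert prof["lut_peak_um"] == pytest.approx(20.0, abs=1.0)
        assert prof["zea_peak_um"] == pytest.approx(20.0, abs=1.0)
        assert abs(prof["lut_peak_um"] - prof["zea_peak_um"]) <= 1.0
        # amplitude ratio at the layer matches the generator fraction within 10%
        ratio = prof["zea"].max() / (prof["zea"].max() + prof["lut"].max())
        assert ratio == pytest.approx(0.4, rel=0.1)
        assert prof["total_fwhm_um"] == pytest.approx(10.0, rel=0.15)

    def test_xy_map_rejected(self, basis):
        smap = _uniform_map(basis, 0.4)
        with pytest.raises(DataError):
            zscan_profile(smap, {"basis": basis})
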