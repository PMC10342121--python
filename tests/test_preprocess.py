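import numpy as np
import pytest

from xanthomap.errors import DataError
from xanthomap.preprocess import (
    correct_baseline,
    crop_region,
    modified_zscores,
    preprocess_spectrum,
    remove_cosmic_rays,
)
from xanthomap.spectra import RamanSpectrum
from xanthomap.synthetic import synth_spectrum


def _gauss_spectrum(basis, extra=None):
    nu = basis.wavenumbers
    y = np.exp(-((nu - 1526.0) ** 2) / (2 * (14.0 / 2.3548200450309493) ** 2))
    if extra is not None:
        y = y + extra
    return RamanSpectrum(nu, y, 514)


def _oracle_flags(y, z_threshold):
    """Brute-force greedy oracle: repeatedly remove the worst bin until the
    local second-difference z of every original candidate drops below
    threshold; the removed bins are the spikes."""

    from scipy.ndimage import median_filter

    floor = float(np.ptp(median_filter(y, size=5, mode="nearest"))) / 20.0

    def zscores(trace):
        d2 = np.zeros_like(trace)
        for i in range(1, trace.size - 1):
            d2[i] = trace[i - 1] - 2 * trace[i] + trace[i + 1]
        med = np.median(d2)
        mad = max(np.median(np.abs(d2 - med)), floor)
        return np.zeros_like(trace) if mad == 0 else 0.6745 * (d2 - med) / mad

    candidates = np.abs(zscores(y)) > z_threshold
    trace = y.copy()
    flags = []
    for _ in range(10):
        z = np.abs(zscores(trace))
        z[~candidates] = 0.0
        for i in flags:
            z[i] = 0.0
        if z.max() <= z_threshold:
            break
        i = int(np.argmax(z))
        clean_bins = [
            j
            for j in range(max(i - 2, 0), min(i + 3, y.size))
            if not candidates[j]
        ]
        span = 2
        while not clean_bins:
            span += 1
            clean_bins = [
                j
                for j in range(max(i - span, 0), min(i + span + 1, y.size))
                if not candidates[j]
            ]
        trace[i] = np.median(trace[clean_bins])
        flags.append(i)
    return sorted(flags)


class TestCosmicRays:
    def test_single_spike_replaced_others_untouched(self, basis):
        spec, _ = synth_spectrum(basis, 0.4, 514, noise_sd=0.01, seed=11)
        y = spec.intensity.copy()
        y[500] += 50 * np.abs(y).max()
        spiked = spec.copy(intensity=y)
        cleaned = remove_cosmic_rays(spiked)
        assert cleaned.metadata["cosmic_ray_bins"] == [500]
        mask = np.ones(y.size, dtype=bool)
        mask[500] = False
        np.testing.assert_array_equal(cleaned.intensity[mask], y[mask])
        assert cleaned.intensity[500] < 2 * np.abs(spec.intensity).max()

    def test_spike_free_spectrum_unchanged(self, basis):
        spec, _ = synth_spectrum(basis, 0.4, 514, noise_sd=0.01, seed=12)
        cleaned = remove_cosmic_rays(spec)
        assert cleaned.metadata["cosmic_ray_bins"] == []
        np.testing.assert_array_equal(cleaned.intensity, spec.intensity)

    def test_adjacent_spikes_match_bruteforce_oracle(self, basis):
        spec, _ = synth_spectrum(basis, 0.4, 514, noise_sd=0.01, seed=13)
        y = spec.intensity.copy()
        y[300] += 40 * np.abs(y).max()
        y[301] += 55 * np.abs(y).max()
        cleaned = remove_cosmic_rays(spec.copy(intensity=y))
        flagged = cleaned.metadata["cosmic_ray_bins"]
        assert set(flagged) == {300, 301}
        assert sorted(flagged) == _oracle_flags(y, 8.0)

    @pytest.mark.parametrize("noise_sd", [0.0, 0.01])
    def test_idempotent(self, basis, noise_sd):
        for seed in (21, 22, 23):
            spec, _ = synth_spectrum(
                basis, 0.5, 488, noise_sd=noise_sd, cosmic_ray_rate=3.0, seed=seed
            )
            once = remove_cosmic_rays(spec)
            twice = remove_cosmic_rays(once)
            np.testing.assert_array_equal(once.intensity, twice.intensity)

    def test_short_spectrum_rejected(self):
        spec = RamanSpectrum(np.arange(800.0, 803.0), np.zeros(3), 514)
        with pytest.raises(DataError):
            remove_cosmic_rays(spec, window=5)

    def test_zscore_robust_to_flat_input(self):
        assert np.all(modified_zscores(np.full(50, 3.0)) == 0)


class TestBaseline:
    def test_linear_ramp_band_area_recovered(self, basis):
        nu = basis.wavenumbers
        band = np.exp(-((nu - 1526.0) ** 2) / (2 * (14.0 / 2.3548200450309493) ** 2))
        ramp = 0.2 + 0.0004 * (nu - 800.0)
        out = correct_baseline(RamanSpectrum(nu, band + ramp, 514))
        win = (nu > 1480) & (nu < 1580)
        area_true = np.trapezoid(band[win], nu[win])
        area = np.trapezoid(out.intensity[win], nu[win])
        assert area == pytest.approx(area_true, rel=0.01)

    def test_zero_baseline_near_noop(self, basis):
        # an asymmetric estimator never returns an exactly zero baseline
        # under a band; the achievable floor is a fraction of a percent
        spec = _gauss_spectrum(basis)
        out = correct_baseline(spec)
        assert np.max(np.abs(out.intensity - spec.intensity)) < 1e-3 * spec.intensity.max()

    def test_positive_baseline_never_raises_signal(self, basis):
        spec = _gauss_spectrum(basis, extra=0.5)
        out = correct_baseline(spec)
        assert np.all(out.intensity <= spec.intensity + 1e-8)

    def test_baseline_stored_in_metadata(self, basis):
        out = correct_baseline(_gauss_spectrum(basis, extra=0.1))
        assert "baseline" in out.metadata
        assert out.metadata["baseline"].shape == out.intensity.shape

    def test_polynomial_method_ramp(self, basis):
        nu = basis.wavenumbers
        band = np.exp(-((nu - 1526.0) ** 2) / (2 * 6.0**2))
        ramp = 0.3 + 0.0002 * (nu - 800.0)
        out = correct_baseline(
            RamanSpectrum(nu, band + ramp, 514), method="polynomial", params={"degree": 1}
        )
        win = (nu > 1480) & (nu < 1580)
        assert np.trapezoid(out.intensity[win], nu[win]) == pytest.approx(
            np.trapezoid(band[win], nu[win]), rel=0.02
        )

    def test_excessive_polynomial_degree_rejected(self, basis):
        with pytest.raises(DataError):
            correct_baseline(_gauss_spectrum(basis), method="polynomial", params={"degree": 9})


class TestCrop:
    def test_default_crop_bounds(self):
        nu = np.arange(700.0, 1901.0)
        spec = RamanSpectrum(nu, np.ones_like(nu), 514)
        out = crop_region(spec)
        assert out.wavenumbers[0] == 800.0
        assert out.wavenumbers[-1] == 1800.0

    def test_full_range_crop_is_identity(self, basis):
        spec = _gauss_spectrum(basis)
        out = crop_region(spec, spec.wavenumbers[0], spec.wavenumbers[-1])
        np.testing.assert_array_equal(out.intensity, spec.intensity)
        np.testing.assert_array_equal(out.wavenumbers, spec.wavenumbers)

    def test_inverted_bounds_rejected(self, basis):
        with pytest.raises(DataError):
            crop_region(_gauss_spectrum(basis), 1500.0, 1400.0)

    def test_disjoint_window_rejected(self, basis):
        with pytest.raises(DataError):
            crop_region(_gauss_spectrum(basis), 2000.0, 2100.0)


class TestEndToEnd:
    def test_nu1_area_recovered_after_spikes_and_ramp(self, basis):
        """Full preprocessing recovers the nu1 area within 2% of clean truth."""
        clean, _ = synth_spectrum(basis, 0.4, 514, seed=0)
        dirty, _ = synth_spectrum(
            basis, 0.4, 514,
            baseline_spec=lambda nu: 0.3 + 0.0005 * (nu - 800.0),
            cosmic_ray_rate=3.0, seed=42,
        )
        out = preprocess_spectrum(dirty)
        win = (clean.wavenumbers >= 1486) & (clean.wavenumbers <= 1566)
        area_true = np.trapezoid(clean.intensity[win], clean.wavenumbers[win])
        win2 = (out.wavenumbers >= 1486) & (out.wavenumbers <= 1566)
        area = np.trapezoid(out.intensity[win2], out.wavenumbers[win2])
        assert area == pytest.approx(area_true, rel=0.02)

    def test_axis_only_changed_by_cropping(self, basis):
        spec, _ = synth_spectrum(basis, 0.2, 488, noise_sd=0.01, seed=1)
        out = preprocess_spectrum(spec, {"crop": None})
        np.testing.assert_array_equal(out.wavenumbers, spec.wavenumbers)
        out2 = preprocess_spectrum(spec, {"crop": (900.0, 1700.0)})
        assert out2.wavenumbers[0] >= 900.0
        assert out2.wavenumbers[-1] <= 1700.0
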