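import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xanthomap.errors import DataError
from xanthomap.flim import (
    anisotropy,
    fit_decay,
    power_trend,
    sector_statistics,
    short_fraction,
    short_fraction_series,
)
from xanthomap.flimdata import DecayHistogram
from xanthomap.synthetic import synth_axon_flim


def _histogram_from_expectation(lam_par, lam_perp=None, bin_ps=16.0):
    n = lam_par.size
    t = np.arange(n) * bin_ps
    if lam_perp is None:
        lam_perp = np.zeros_like(lam_par)
    return DecayHistogram(t, np.round(lam_par).astype(int), np.round(lam_perp).astype(int))


class TestAnisotropy:
    @pytest.mark.parametrize(
        "ipar,iperp,g,expected",
        [(100.0, 100.0, 1.0, 0.0), (300.0, 100.0, 1.0, 0.4), (100.0, 0.0, 2.5, 1.0)],
    )
    def test_formula_arithmetic(self, ipar, iperp, g, expected):
        assert anisotropy(ipar, iperp, g) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(DataError):
            anisotropy(0.0, 0.0)

    def test_bounds_for_random_intensities(self, rng):
        """With G = 1, r always lies in [-0.5, 1]."""
        ipar = rng.uniform(0, 1e4, 10_000)
        iperp = rng.uniform(0, 1e4, 10_000)
        r = (ipar - iperp) / (ipar + 2 * iperp)
        for a, b in zip(ipar[:200], iperp[:200]):
            r_one = anisotropy(float(a), float(b), 1.0)
            assert -0.5 <= r_one <= 1.0
        assert np.nanmin(r) >= -0.5 and np.nanmax(r) <= 1.0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(ipar=st.floats(0.0, 1e6), iperp=st.floats(0.0, 1e6))
    def test_channel_swap_consistency(self, ipar, iperp):
        """Swapping channels maps r through the formula itself, not -r."""
        if ipar + iperp == 0:
            return
        r = anisotropy(ipar, iperp, 1.0)
        r_swap = anisotropy(iperp, ipar, 1.0)
        expected = (iperp - ipar) / (iperp + 2 * ipar)
        assert r_swap == pytest.approx(expected, abs=1e-12)
        assert -0.5 <= r <= 1.0


class TestFitDecay:
    def test_single_exponential_exact(self):
        t = np.arange(780) * 16.0
        lam = 1e5 * np.exp(-(t + 8.0) / 2500.0)
        fit = fit_decay(_histogram_from_expectation(lam), n_components=1)
        assert fit.tau_ps == pytest.approx(2500.0, abs=1.0)

    def test_biexponential_recovery(self):
        """10^6 photons at f_short = 0.6 (70/2500 ps): recovered within 0.02."""
        datasets, truth = synth_axon_flim(
            counts_per_pixel=4000, ring_radius_px=20, ring_width_px=4,
            tau_short_ps=70.0, tau_long_ps=2500.0, f_short=0.6, seed=3,
        )
        hist = datasets[0].pooled_histogram(truth.extras["ring_mask"])
        assert hist.counts_total.sum() > 1e6
        fit = fit_decay(hist, n_components=2)
        assert fit.f_short == pytest.approx(0.6, abs=0.02)
        assert fit.tau_long_ps == pytest.approx(2500.0, rel=0.05)

    def test_two_components_on_monoexponential(self):
        t = np.arange(780) * 16.0
        lam = 1e5 * np.exp(-(t + 8.0) / 2500.0)
        fit = fit_decay(_histogram_from_expectation(lam), n_components=2)
        assert fit.f_short < 0.05 or fit.degenerate

    def test_insufficient_counts_rejected(self):
        t = np.arange(128) * 16.0
        h = DecayHistogram(t, np.zeros(128, int), np.zeros(128, int))
        with pytest.raises(DataError):
            fit_decay(h)

    def test_se_scales_with_counts(self):
        """Quadrupling the photon count halves the f_short standard error."""
        ses = []
        for counts in (1000, 4000):
            datasets, truth = synth_axon_flim(
                counts_per_pixel=counts, ring_radius_px=15, ring_width_px=4, seed=9
            )
            fit = fit_decay(datasets[0].pooled_histogram(truth.extras["ring_mask"]), 2)
            ses.append(fit.fisher_se_f_short)
        assert ses[1] / ses[0] == pytest.approx(0.5, abs=0.2 * 0.5)


class TestShortFraction:
    @pytest.mark.parametrize("a_s,a_l,expected", [(3.0, 1.0, 0.75), (0.0, 1.0, 0.0), (1.0, 1.0, 0.5)])
    def test_amplitude_fraction(self, a_s, a_l, expected):
        from xanthomap.flim import BiexpFit

        fit = BiexpFit(
            tau_short_ps=70.0, tau_long_ps=2500.0, amp_short=a_s, amp_long=a_l,
            f_short=a_s / (a_s + a_l) if a_s + a_l else 0.0,
            background=0.0, deviance=0.0, n_components=2, converged=True,
        )
        assert short_fraction(fit) == pytest.approx(expected)

    def test_degenerate_fit_warns(self):
        from xanthomap.flim import BiexpFit

        fit = BiexpFit(
            tau_short_ps=100.0, tau_long_ps=105.0, amp_short=1.0, amp_long=1.0,
            f_short=0.5, background=0.0, deviance=0.0, n_components=2,
            converged=True, degenerate=True,
        )
        with pytest.warns(UserWarning):
            short_fraction(fit)


class TestSectors:
    def test_radial_axon_bright_left_right(self):
        datasets, _ = synth_axon_flim(
            orientation="radial", counts_per_pixel=500, ring_radius_px=12,
            ring_width_px=3, n_bins=128, seed=4,
        )
        res = sector_statistics(datasets[0])
        assert res.contrast_ratio > 1.5
        assert res.sector_intensity["left"] > res.sector_intensity["top"]

    def test_tangential_axon_rotated_pattern(self):
        datasets, _ = synth_axon_flim(
            orientation="tangential", counts_per_pixel=500, ring_radius_px=12,
            ring_width_px=3, n_bins=128, seed=4,
        )
        res = sector_statistics(datasets[0])
        assert res.contrast_ratio < 0.7

    def test_isotropic_ring_sectors_equal(self, rng):
        """Unoriented emitters give statistically equal sector means."""
        n, nt = 41, 32
        par = np.zeros((n, n, nt), dtype=np.uint32)
        perp = np.zeros_like(par)
        c = (n - 1) / 2
        yy, xx = np.mgrid[0:n, 0:n]
        ring = np.abs(np.hypot(xx - c, yy - c) - 12) <= 2
        lam = np.exp(-np.arange(nt) * 16.0 / 800.0) * 10
        for r, cidx in zip(*np.nonzero(ring)):
            par[r, cidx] = rng.poisson(lam)
            perp[r, cidx] = rng.poisson(lam)
        from xanthomap.flimdata import FLIMDataset

        ds = FLIMDataset(np.arange(nt) * 16.0, par, perp)
        res = sector_statistics(ds)
        vals = np.array(list(res.sector_intensity.values()))
        pooled_se = vals.std(ddof=1)
        assert np.ptp(vals) < 3 * pooled_se + 0.2 * vals.mean()

    def test_anisotropy_image_extremes(self):
        """theta = 0 pixels (right/left sectors) approach r = 1 for radial dipoles."""
        datasets, truth = synth_axon_flim(
            orientation="radial", counts_per_pixel=3000, ring_radius_px=12,
            ring_width_px=2, n_bins=128, seed=5, g_factor=1.0,
        )
        res = sector_statistics(datasets[0])
        assert res.sector_r["right"] > 0.5
        assert res.sector_r["top"] < 0.0


class TestPowerTrend:
    def test_constant_truth_slope_ci_contains_zero(self):
        datasets, truth = synth_axon_flim(
            counts_per_pixel=2000, power_series=(0.5, 1.0, 2.0, 4.0), seed=6,
        )
        series = short_fraction_series(datasets, truth.extras["ring_mask"])
        trend = power_trend(series)
        lo, hi = trend["slope_ci"]
        assert lo <= 0.0 <= hi

    def test_increasing_truth_detected(self):
        datasets, truth = synth_axon_flim(
            counts_per_pixel=2000, power_series=(0.5, 1.0, 2.0, 4.0), seed=6,
            f_short_vs_power=lambda p: 0.3 + 0.1 * p,
        )
        series = short_fraction_series(datasets, truth.extras["ring_mask"])
        trend = power_trend(series)
        lo, hi = trend["slope_ci"]
        assert lo > 0.0

    def test_two_powers_rejected(self):
        with pytest.raises(DataError):
            power_trend([(1.0, 0.5, 0.01), (2.0, 0.5, 0.01)])

    def test_f_short_independent_of_orientation_angle(self):
        """Lifetime composition does not vary around the ring (photoselection
        affects intensity, not the decay)."""
        datasets, truth = synth_axon_flim(
            counts_per_pixel=3000, ring_radius_px=14, ring_width_px=4, seed=8,
        )
        ds = datasets[0]
        dipole = truth.extras["dipole_angle"]
        ring = truth.extras["ring_mask"]
        f_by_wedge, x_by_wedge = [], []
        edges = np.linspace(-np.pi, np.pi, 9)
        for lo, hi in zip(edges[:-1], edges[1:]):
            wedge = ring & (dipole >= lo) & (dipole < hi)
            hist = ds.pooled_histogram(wedge)
            if hist.counts_total.sum() < 5000:
                continue
            fit = fit_decay(hist, 2)
            f_by_wedge.append(fit.f_short)
            x_by_wedge.append((lo + hi) / 2)
        assert len(f_by_wedge) >= 4
        slope, _ = np.polyfit(x_by_wedge, f_by_wedge, 1)
        resid = np.array(f_by_wedge) - np.polyval(
            np.polyfit(x_by_wedge, f_by_wedge, 1), x_by_wedge
        )
        se = resid.std(ddof=1) / (np.std(x_by_wedge) * np.sqrt(len(f_by_wedge)))
        assert abs(slope) <= 2 * se + 0.02
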