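"""Synthetic-data generators for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* two-component carotenoid Raman spectra over 800-1800 cm^-1 with
  laser-dependent (488/514 nm) scattering cross-sections,
* a radially structured macular map with foveola/fovea/parafovea plateaus
  (central Zea:Lut ratio ~2, peripheral ~0.3, ~100x total-concentration
  contrast between the macula center and the periphery),
* depth scans (XZ) with both pigments co-localized in one layer,
* annular axon cross-section FLIM images with oriented-dipole
  photoselection and biexponential decays.

Every generated artifact carries a :class:`SyntheticTruth` record, and
regeneration with the same seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np

from .basis import PigmentBasis
from .errors import ConfigurationError, DataError
from .flimdata import FLIMDataset
from .spectra import RamanSpectrum, SpectralMap

__all__ = [
    "RetinaGeometry",
    "SyntheticTruth",
    "synth_spectrum",
    "synth_mixture_series",
    "synth_retina_map",
    "synth_zscan",
    "synth_axon_flim",
]


# --------------------------------------------------------------------------
# truth records and geometry


@dataclass
class SyntheticTruth:
    """Ground truth attached to one generated spectrum / dataset."""

    f_zea: float | np.ndarray
    total_concentration: float | np.ndarray
    laser_nm: int | None = None
    noise_sd: float = 0.0
    seed: int | None = None
    extras: dict[str, Any] = field(default_factory=dict)


@dataclass
class RetinaGeometry:
    """Radial model of the macular pigment distribution.

    Region diameters follow the anatomical convention: foveola ~0.35 mm,
    fovea ~1 mm, parafovea ~2 mm central disks.  The Zea:Lut ratio sits on
    a central plateau (default 2.0) inside the foveola, descends through
    one smooth log-space raised-cosine spanning the foveola-to-parafovea
    radii, and rests on the peripheral plateau (default 0.3) beyond the
    parafovea radius.  Total xanthophyll concentration is ~100x higher in
    the macula than in the periphery: plateaus at relative levels
    1.0 (foveola) / ``fovea_total_level`` / ``parafovea_total_level`` /
    1/contrast (outside), joined by raised-cosine steps of width
    ``transition_width`` that *start* at the foveola and fovea boundary
    radii and *end* at the parafovea radius, so the peripheral plateau is
    fully reached at the parafovea boundary.
    """

    foveola_diameter_mm: float = 0.35
    fovea_diameter_mm: float = 1.0
    parafovea_diameter_mm: float = 2.0
    central_zea_lut_ratio: float = 2.0
    peripheral_zea_lut_ratio: float = 0.3
    central_to_peripheral_total_ratio: float = 100.0
    transition_width_mm: float = 0.15
    map_extent_mm: float = 3.0
    pixel_size_um: float = 5.0
    fovea_total_level: float = 0.95
    parafovea_total_level: float = 0.10

    def __post_init__(self):
        d1, d2, d3 = (
            self.foveola_diameter_mm,
            self.fovea_diameter_mm,
            self.parafovea_diameter_mm,
        )
        if not (0 < d1 < d2 < d3):
            raise ConfigurationError(
                f"region diameters must be strictly increasing, got {d1}/{d2}/{d3} mm"
            )
        for name in (
            "central_zea_lut_ratio",
            "peripheral_zea_lut_ratio",
            "central_to_peripheral_total_ratio",
            "transition_width_mm",
            "map_extent_mm",
            "pixel_size_um",
            "fovea_total_level",
            "parafovea_total_level",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.parafovea_total_level < self.fovea_total_level <= 1.0:
            raise ConfigurationError(
                "total plateau levels must satisfy parafovea < fovea <= 1"
            )

    # boundary radii in mm
    @property
    def r_foveola(self) -> float:
        return self.foveola_diameter_mm / 2.0

    @property
    def r_fovea(self) -> float:
        return self.fovea_diameter_mm / 2.0

    @property
    def r_parafovea(self) -> float:
        return self.parafovea_diameter_mm / 2.0

    def truth_ratio(self, r_mm: np.ndarray) -> np.ndarray:
        """True Zea:Lut concentration ratio at radius r (mm)."""
        r = np.asarray(r_mm, dtype=float)
        lo, hi = self.r_foveola, self.r_parafovea
        s = _raised_cosine(r, lo, hi)
        log_ratio = (1.0 - s) * np.log(self.central_zea_lut_ratio) + s * np.log(
            self.peripheral_zea_lut_ratio
        )
        return np.exp(log_ratio)

    def truth_f_zea(self, r_mm: np.ndarray) -> np.ndarray:
        """True zeaxanthin fraction f = ratio / (1 + ratio)."""
        ratio = self.truth_ratio(r_mm)
        return ratio / (1.0 + ratio)

    def truth_total(self, r_mm: np.ndarray) -> np.ndarray:
        """True total concentration (arbitrary units; peripheral plateau = 1)."""
        r = np.asarray(r_mm, dtype=float)
        contrast = self.central_to_peripheral_total_ratio
        levels = np.array(
            [contrast, contrast * self.fovea_total_level,
             contrast * self.parafovea_total_level, 1.0]
        )
        w = self.transition_width_mm
        # steps start at the foveola/fovea radii and end at the parafovea radius
        edges = [
            (self.r_foveola, self.r_foveola + w),
            (self.r_fovea, self.r_fovea + w),
            (self.r_parafovea - w, self.r_parafovea),
        ]
        log_t = np.full_like(r, np.log(levels[0]))
        for (lo, hi), (a, b) in zip(edges, zip(levels[:-1], levels[1:])):
            s = _raised_cosine(r, lo, hi)
            log_t = log_t + s * (np.log(b) - np.log(a))
        return np.exp(log_t)


def _raised_cosine(r: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Smooth 0->1 step: 0 below lo, raised-cosine on [lo, hi], 1 above hi."""
    x = np.clip((r - lo) / (hi - lo), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))


# --------------------------------------------------------------------------
# Raman spectrum generators


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _expected_intensity(
    basis: PigmentBasis,
    f_zea: float | np.ndarray,
    laser_nm: int,
    total_concentration: float | np.ndarray,
) -> np.ndarray:
    """Noise-free mixture spectrum c * [f s_z B_z + (1-f) s_l B_l]."""
    s_l = basis.cross_section("lut", laser_nm)
    s_z = basis.cross_section("zea", laser_nm)
    b_l = basis.component_shape("lut")
    b_z = basis.component_shape("zea")
    f = np.asarray(f_zea, dtype=float)
    c = np.asarray(total_concentration, dtype=float)
    return c[..., None] * (
        f[..., None] * s_z * b_z + (1.0 - f[..., None]) * s_l * b_l
    )


def _evaluate_baseline(baseline_spec, wavenumbers: np.ndarray) -> np.ndarray:
    if baseline_spec is None:
        return np.zeros_like(wavenumbers)
    if callable(baseline_spec):
        return np.asarray(baseline_spec(wavenumbers), dtype=float)
    arr = np.asarray(baseline_spec, dtype=float)
    if arr.shape != wavenumbers.shape:
        raise DataError("baseline array must match the wavenumber axis")
    return arr


def synth_spectrum(
    basis: PigmentBasis,
    f_zea: float,
    laser_nm: int = 514,
    total_concentration: float = 1.0,
    noise_sd: float = 0.0,
    baseline_spec=None,
    cosmic_ray_rate: float = 0.0,
    seed: int | None = None,
    poisson: bool = False,
) -> tuple[RamanSpectrum, SyntheticTruth]:
    """Generate one mixture spectrum with optional noise, baseline and spikes.

    The expected intensity is
    ``total_concentration * [f_zea s(zea,L) B_zea + (1-f_zea) s(lut,L) B_lut]
    + baseline``; Gaussian noise of sd ``noise_sd`` is added (or, with
    ``poisson=True``, the expectation is replaced by a Poisson draw before
    adding the Gaussian term).  Cosmic rays are injected as single-bin
    spikes, their number Poisson-distributed with mean ``cosmic_ray_rate``.
    """
    if not 0.0 <= f_zea <= 1.0:
        raise DataError(f"f_zea must lie in [0, 1], got {f_zea}")
    if noise_sd < 0:
        raise DataError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = _rng(seed)
    nu = basis.wavenumbers
    expected = _expected_intensity(
        basis, np.float64(f_zea), laser_nm, np.float64(total_concentration)
    )
    intensity = expected + _evaluate_baseline(baseline_spec, nu)
    if poisson:
        intensity = rng.poisson(np.clip(intensity, 0, None)).astype(float)
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=nu.shape)
    spike_bins: list[int] = []
    if cosmic_ray_rate > 0:
        n_spikes = rng.poisson(cosmic_ray_rate)
        if n_spikes:
            spike_bins = sorted(rng.choice(nu.size, size=n_spikes, replace=False).tolist())
            scale = max(float(np.max(expected)), noise_sd, 1e-12)
            intensity[spike_bins] += rng.uniform(20.0, 80.0, size=len(spike_bins)) * scale
    truth = SyntheticTruth(
        f_zea=float(f_zea),
        total_concentration=float(total_concentration),
        laser_nm=laser_nm,
        noise_sd=noise_sd,
        seed=seed,
        extras={"spike_bins": spike_bins},
    )
    spectrum = RamanSpectrum(
        nu.copy(),
        intensity,
        laser_nm,
        {"synthetic": True, "f_zea": float(f_zea), "seed": seed},
    )
    return spectrum, truth


def synth_mixture_series(
    basis: PigmentBasis,
    laser_nm: int = 514,
    n_levels: int = 11,
    n_reps: int = 10,
    noise_sd: float = 0.02,
    seed: int | None = None,
    total_concentration: float = 1.0,
) -> list[tuple[RamanSpectrum, SyntheticTruth]]:
    """Mixture series on the equally spaced fraction grid 0..1.

    Emulates a dilution-series validation experiment: ``n_levels`` true
    zeaxanthin fractions, ``n_reps`` replicate spectra per level differing
    only in the noise realization.
    """
    if n_levels < 2:
        raise DataError(f"n_levels must be >= 2, got {n_levels}")
    if n_reps < 1:
        raise DataError(f"n_reps must be >= 1, got {n_reps}")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_levels * n_reps)
    out = []
    for k in range(n_levels):
        f = k / (n_levels - 1)
        for rep in range(n_reps):
            child = children[k * n_reps + rep]
            spec, truth = synth_spectrum(
                basis,
                f_zea=f,
                laser_nm=laser_nm,
                total_concentration=total_concentration,
                noise_sd=noise_sd,
                seed=child,
            )
            truth.seed = seed
            truth.extras.update({"level": k, "rep": rep})
            spec.metadata.update({"level": k, "rep": rep})
            out.append((spec, truth))
    return out


def synth_retina_map(
    basis: PigmentBasis,
    geometry: RetinaGeometry | None = None,
    laser_nm: int = 514,
    seed: int | None = None,
    noise_sd: float = 0.01,
) -> tuple[SpectralMap, dict[str, np.ndarray]]:
    """Generate an XY spectral map of the macula with truth images.

    Per-pixel truth follows :class:`RetinaGeometry`; per-pixel spectra are
    drawn with the same model as :func:`synth_spectrum` (Gaussian noise of
    sd ``noise_sd``, flat zero baseline).  Returns the map plus a dict of
    truth images: ``f_zea``, ``ratio``, ``total``, ``radius_mm``.

    The map must contain at least one pixel beyond the parafovea radius so
    the periphery is represented; otherwise a configuration error is
    raised.  Scaled-down extents (smaller than the parafovea diameter but
    with peripheral corner pixels) are allowed.
    """
    geometry = geometry or RetinaGeometry()
    pitch_um = geometry.pixel_size_um
    if pitch_um <= 0:
        raise ConfigurationError("pixel_size_um must be > 0")
    n_pix = int(round(geometry.map_extent_mm * 1000.0 / pitch_um))
    if n_pix < 4:
        raise ConfigurationError("map extent too small for the requested pixel size")
    coords = ((np.arange(n_pix) + 0.5) * pitch_um - geometry.map_extent_mm * 500.0) / 1000.0
    xx, yy = np.meshgrid(coords, coords)  # mm, map centered on the fovea center
    r_mm = np.hypot(xx, yy)
    if not np.any(r_mm > geometry.r_parafovea):
        raise ConfigurationError(
            "map extent leaves no pixels beyond the parafovea radius; "
            "enlarge map_extent_mm"
        )
    f_zea = geometry.truth_f_zea(r_mm)
    total = geometry.truth_total(r_mm)
    expected = _expected_intensity(basis, f_zea, laser_nm, total)
    rng = _rng(seed)
    if noise_sd > 0:
        expected = expected + rng.normal(0.0, noise_sd, size=expected.shape)
    smap = SpectralMap(
        plane="XY",
        wavenumbers=basis.wavenumbers.copy(),
        intensity=expected,
        pixel_size_um=(pitch_um, pitch_um),
        laser_nm=laser_nm,
        metadata={"synthetic": True, "seed": seed, "noise_sd": noise_sd},
    )
    truth = {
        "f_zea": f_zea,
        "ratio": geometry.truth_ratio(r_mm),
        "total": total,
        "radius_mm": r_mm,
        "geometry": geometry,
    }
    return smap, truth


def synth_zscan(
    basis: PigmentBasis,
    layer_center_um: float = 20.0,
    layer_fwhm_um: float = 10.0,
    f_zea_profile: float | Callable[[np.ndarray], np.ndarray] = 0.5,
    laser_nm: int = 514,
    seed: int | None = None,
    depth_um: float = 50.0,
    width_um: float = 20.0,
    voxel_pitch_um: float = 1.0,
    peak_concentration: float = 1.0,
    noise_sd: float = 0.0,
) -> tuple[SpectralMap, dict[str, np.ndarray]]:
    """Generate an XZ depth scan with one pigment-bearing layer.

    Both pigments share the same Gaussian layer profile along Z
    (co-localized in the same structures); their relative amounts are set
    by ``f_zea_profile`` (a constant or a function of depth).  The default
    voxel pitch is 1 µm.
    """
    if layer_fwhm_um <= 0 or layer_center_um <= 0:
        raise DataError("layer center and width must be positive")
    if voxel_pitch_um <= 0:
        raise DataError("voxel pitch must be positive")
    n_z = int(round(depth_um / voxel_pitch_um))
    n_x = max(int(round(width_um / voxel_pitch_um)), 1)
    z_um = (np.arange(n_z) + 0.5) * voxel_pitch_um
    sigma = layer_fwhm_um / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    total_z = peak_concentration * np.exp(
        -((z_um - layer_center_um) ** 2) / (2.0 * sigma**2)
    )
    if callable(f_zea_profile):
        f_z = np.asarray(f_zea_profile(z_um), dtype=float)
    else:
        f_z = np.full(n_z, float(f_zea_profile))
    if np.any((f_z < 0) | (f_z > 1)):
        raise DataError("f_zea profile must lie in [0, 1]")
    total = np.repeat(total_z[:, None], n_x, axis=1)
    f_zea = np.repeat(f_z[:, None], n_x, axis=1)
    expected = _expected_intensity(basis, f_zea, laser_nm, total)
    rng = _rng(seed)
    if noise_sd > 0:
        expected = expected + rng.normal(0.0, noise_sd, size=expected.shape)
    smap = SpectralMap(
        plane="XZ",
        wavenumbers=basis.wavenumbers.copy(),
        intensity=expected,
        pixel_size_um=(voxel_pitch_um, voxel_pitch_um),
        laser_nm=laser_nm,
        metadata={"synthetic": True, "seed": seed, "layer_center_um": layer_center_um},
    )
    truth = {
        "z_um": z_um,
        "total_z": total_z,
        "f_zea_z": f_z,
        "lut_z": total_z * (1.0 - f_z),
        "zea_z": total_z * f_z,
        "f_zea": f_zea,
        "total": total,
    }
    return smap, truth


# --------------------------------------------------------------------------
# polarized FLIM axon generator


def _bin_probabilities(time_edges: np.ndarray, tau_ps: float) -> np.ndarray:
    """Truncated-exponential probability of each bin on the histogram window."""
    cdf = 1.0 - np.exp(-time_edges / tau_ps)
    p = np.diff(cdf)
    return p / p.sum()


def photon_fraction_from_amplitude(f_short: float, tau_short: float, tau_long: float) -> float:
    """Photon (intensity) fraction of the short component implied by an
    amplitude fraction ``f_short``: phi = f tau_s / (f tau_s + (1-f) tau_l)."""
    num = f_short * tau_short
    return num / (num + (1.0 - f_short) * tau_long)


def synth_axon_flim(
    orientation: str = "radial",
    ring_radius_px: float = 20.0,
    ring_width_px: float = 4.0,
    counts_per_pixel: float = 400.0,
    tau_short_ps: float = 70.0,
    tau_long_ps: float = 2500.0,
    f_short: float = 0.6,
    power_series: Sequence[float] = (1.0,),
    g_factor: float = 1.0,
    seed: int | None = None,
    image_size_px: int | None = None,
    n_bins: int = 780,
    bin_ps: float = 16.0,
    f_short_vs_power: Callable[[float], float] | None = None,
) -> tuple[list[FLIMDataset], SyntheticTruth]:
    """Generate polarized FLIM images of an axon cross-section (annulus).

    Xanthophyll transition dipoles are fixed in the image plane along the
    membrane normal: at each annulus pixel the dipole angle to the
    horizontal excitation polarization is the angle of the radial direction
    (``orientation="radial"``) or its 90-degree rotation
    (``orientation="tangential"``).  Per-photon excitation probability is
    proportional to cos^2(theta); the parallel / perpendicular detection
    channels collect cos^2(theta) / sin^2(theta) of the emitted photons
    (fixed in-plane dipole model, no 3-D wobble).  The measured
    perpendicular channel is attenuated by the instrumental G factor.
    Arrival times follow the biexponential mixture with amplitude fraction
    ``f_short`` of the short component, binned at ``bin_ps`` (16 ps
    default); one dataset is produced per entry of ``power_series`` with
    expected counts scaled by the power.  Unless ``f_short_vs_power`` is
    given, the true amplitude fraction is constant across powers.
    """
    if orientation not in ("radial", "tangential"):
        raise DataError(f"orientation must be 'radial' or 'tangential', got {orientation!r}")
    if len(power_series) == 0:
        raise DataError("power_series must not be empty")
    if tau_short_ps <= 0 or tau_long_ps <= 0:
        raise DataError("lifetimes must be positive")
    if tau_short_ps >= tau_long_ps:
        raise DataError("tau_short must be smaller than tau_long")
    if not 0.0 <= f_short <= 1.0:
        raise DataError(f"f_short must lie in [0, 1], got {f_short}")
    if counts_per_pixel <= 0:
        raise DataError("counts_per_pixel must be > 0")

    if image_size_px is None:
        image_size_px = int(2 * (ring_radius_px + ring_width_px) + 9)
    n = image_size_px
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    dx, dy = xx - c, yy - c
    rr = np.hypot(dx, dy)
    ring = np.abs(rr - ring_radius_px) <= ring_width_px / 2.0
    theta = np.arctan2(dy, dx)  # angle of the radial direction at each pixel
    dipole = theta if orientation == "radial" else theta + np.pi / 2.0
    cos2 = np.cos(dipole) ** 2
    sin2 = np.sin(dipole) ** 2

    time_edges = np.arange(n_bins + 1) * bin_ps
    time_ps = time_edges[:-1]

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(power_series))
    datasets = []
    truth_f = []
    for power, child in zip(power_series, children):
        rng = np.random.default_rng(child)
        f_true = f_short if f_short_vs_power is None else float(f_short_vs_power(power))
        phi = photon_fraction_from_amplitude(f_true, tau_short_ps, tau_long_ps)
        p_bins = phi * _bin_probabilities(time_edges, tau_short_ps) + (
            1.0 - phi
        ) * _bin_probabilities(time_edges, tau_long_ps)
        exp_total = counts_per_pixel * power * cos2 * ring
        exp_par = exp_total * cos2
        exp_perp = exp_total * sin2 / g_factor
        par = np.zeros((n, n, n_bins), dtype=np.uint32)
        perp = np.zeros_like(par)
        rows, cols = np.nonzero(ring)
        n_par = rng.poisson(exp_par[rows, cols])
        n_perp = rng.poisson(exp_perp[rows, cols])
        for i, (r_, c_) in enumerate(zip(rows, cols)):
            if n_par[i]:
                par[r_, c_] = rng.multinomial(n_par[i], p_bins)
            if n_perp[i]:
                perp[r_, c_] = rng.multinomial(n_perp[i], p_bins)
        datasets.append(
            FLIMDataset(
                time_ps=time_ps,
                parallel=par,
                perpendicular=perp,
                g_factor=g_factor,
                laser_power=float(power),
                metadata={
                    "synthetic": True,
                    "orientation": orientation,
                    "ring_radius_px": ring_radius_px,
                    "ring_width_px": ring_width_px,
                    "true_f_short": f_true,
                    "bin_ps": bin_ps,
                    "excitation_nm": 470,
                    "emission_band": "550/88",
                },
            )
        )
        truth_f.append(f_true)

    truth = SyntheticTruth(
        f_zea=np.nan,  # not a Raman artifact
        total_concentration=counts_per_pixel,
        noise_sd=0.0,
        seed=seed,
        extras={
            "tau_short_ps": tau_short_ps,
            "tau_long_ps": tau_long_ps,
            "f_short_per_power": truth_f,
            "power_series": list(power_series),
            "g_factor": g_factor,
            "orientation": orientation,
            "dipole_angle": dipole,
            "ring_mask": ring,
        },
    )
    return datasets, truth
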