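"""Spatial analysis: pigment images, radial profiles, regions, Z-scans.

Turns a preprocessed spectral map into per-pixel pigment images (lutein /
zeaxanthin / total concentration, nu1 band area, band FWHM, zeaxanthin
fraction), locates the macula center, reduces images to radial profiles,
segments the foveola / fovea / parafovea regions (by fixed anatomical
diameters or data-driven from the concentration profile), and extracts
line cross-sections and Z-scan layer profiles.

Coordinates are continuous µm with the origin at the lower-left pixel
corner, x rightward, y upward, pixel centers at (i + 0.5) * pitch; Z
increases into the sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .basis import make_default_basis
from .calibration import CalibrationCurve, invert_calibration
from .cls import cls_fit
from .errors import DataError, NumericalError
from .nu1 import fit_nu1_gaussians, locate_nu1, measure_nu1_fwhm
from .spectra import SpectralMap

__all__ = [
    "PigmentMap",
    "RegionSegmentation",
    "RadialProfile",
    "map_pixelwise",
    "find_center",
    "radial_profile",
    "segment_regions",
    "region_ratios",
    "line_cross_section",
    "zscan_profile",
]

REGION_NAMES = ("foveola", "fovea", "parafovea", "outside")
DEFAULT_REGION_DIAMETERS_MM = (0.35, 1.0, 2.0)


@dataclass
class PigmentMap:
    """Per-pixel images derived from a spectral map.

    ``images`` holds same-grid float arrays: ``lut`` / ``zea`` / ``total``
    (cross-section-corrected concentrations, arbitrary units),
    ``nu1_area`` (raw resonance-weighted nu1 band area), ``fwhm`` (cm^-1),
    ``fraction_zea`` (corrected) and ``raw_fraction_zea``.  ``failed`` is
    True at pixels where the per-pixel fit failed; such pixels carry NaN
    and are excluded from every downstream statistic.
    """

    plane: str
    pixel_size_um: tuple[float, float]
    images: dict[str, np.ndarray]
    failed: np.ndarray
    laser_nm: int
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.failed.shape

    def pixel_centers_um(self) -> tuple[np.ndarray, np.ndarray]:
        n_rows, n_cols = self.shape
        pr, pc = self.pixel_size_um
        return (np.arange(n_rows) + 0.5) * pr, (np.arange(n_cols) + 0.5) * pc

    def coordinate_grids_um(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates of every pixel, each of shape (rows, cols)."""
        rows_um, cols_um = self.pixel_centers_um()
        xx, yy = np.meshgrid(cols_um, rows_um)
        return xx, yy


@dataclass
class RegionSegmentation:
    """Radial region labels around the macula center."""

    center_um: tuple[float, float]
    boundary_radii_um: tuple[float, float, float]
    labels: np.ndarray  # int image: 0 foveola, 1 fovea, 2 parafovea, 3 outside
    method: str  # "fixed" or "data_driven"

    def region_mask(self, name: str) -> np.ndarray:
        return self.labels == REGION_NAMES.index(name)


@dataclass
class RadialProfile:
    """Annulus-averaged image statistics vs radius."""

    radius_um: np.ndarray  # bin centers
    bin_width_um: float
    n: np.ndarray  # pixels per bin
    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]

    @property
    def ratio(self) -> np.ndarray:
        """Zea:Lut ratio of annulus means (ratio of means, not mean of ratios)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.mean["zea"] / self.mean["lut"]


def _pixel_cross_sections(estimator_config: dict, laser_nm: int) -> tuple[float, float]:
    cfg = estimator_config
    if "cross_sections" in cfg:
        cs = cfg["cross_sections"]
        return float(cs[0]), float(cs[1])
    basis = cfg.get("basis") or make_default_basis()
    return basis.cross_section("lut", laser_nm), basis.cross_section("zea", laser_nm)


def map_pixelwise(
    smap: SpectralMap,
    estimator_config: dict | None = None,
    calibration: CalibrationCurve | None = None,
    failure_threshold: float = 0.2,
) -> PigmentMap:
    """Per-pixel unmixing of a spectral map into pigment images.

    For each pixel: locate and fit the nu1 band (or CLS on the full
    spectrum), record the raw band area, correct the raw fraction through
    the calibration curve (or, without one, through the cross-sections),
    convert to concentrations, and measure the observed band FWHM.  Total
    concentration is the cross-section-corrected A_lut/s_lut + A_zea/s_zea
    so that it tracks pigment amount rather than resonance-weighted signal;
    the raw area is kept in the ``nu1_area`` image.  Failed pixels are
    masked, never interpolated; more than ``failure_threshold`` failures
    raise a map-quality error.
    """
    cfg = dict(estimator_config or {})
    estimator = cfg.get("estimator", "nu1")
    if calibration is not None and calibration.laser_nm != smap.laser_nm:
        raise DataError(
            f"calibration is for {calibration.laser_nm} nm but the map was "
            f"recorded at {smap.laser_nm} nm"
        )
    s_l, s_z = _pixel_cross_sections(cfg, smap.laser_nm)
    # single-start width grid by default: map pixels are warm problems near
    # the default band width, and the full start grid triples the runtime
    constraints = dict(cfg.get("constraints") or {})
    constraints.setdefault("width_starts", (14.0,))
    constraints.setdefault("fix_centers", True)
    constraints.setdefault("local_offset", True)

    basis = cfg.get("basis") or make_default_basis()
    refs = None
    if estimator == "cls":
        refs = {
            p: basis.reference_spectrum(p, wavenumbers=smap.wavenumbers)
            for p in ("lut", "zea")
        }

    n_rows, n_cols = smap.shape
    names = ("lut", "zea", "total", "nu1_area", "fwhm", "fraction_zea", "raw_fraction_zea")
    images = {n: np.full((n_rows, n_cols), np.nan) for n in names}
    failed = np.zeros((n_rows, n_cols), dtype=bool)

    for r in range(n_rows):
        for c in range(n_cols):
            spectrum = smap.pixel(r, c)
            try:
                window = locate_nu1(spectrum)
                if estimator == "nu1":
                    fit = fit_nu1_gaussians(spectrum, window, constraints)
                    area_l, area_z = fit.area_lut, fit.area_zea
                    raw = fit.raw_fraction_zea
                elif estimator == "cls":
                    res = cls_fit(
                        spectrum, refs, nonneg=True,
                        nuisance_terms=cfg.get("nuisance_terms", ("offset",)),
                    )
                    area_l = max(res.coefficients["lut"], 0.0)
                    area_z = max(res.coefficients["zea"], 0.0)
                    if area_l + area_z == 0:
                        raise NumericalError("all-zero CLS coefficients")
                    raw = res.raw_fraction_zea
                else:
                    raise DataError(f"unknown estimator {estimator!r}")
                fwhm = measure_nu1_fwhm(spectrum, window)
            except (DataError, NumericalError):
                failed[r, c] = True
                continue
            if calibration is not None:
                corrected = invert_calibration(raw, calibration)
            else:
                corr_z = area_z / s_z
                corrected = corr_z / (corr_z + area_l / s_l)
            total = area_l / s_l + area_z / s_z
            images["lut"][r, c] = total * (1.0 - corrected)
            images["zea"][r, c] = total * corrected
            images["total"][r, c] = total
            images["nu1_area"][r, c] = area_l + area_z
            images["fwhm"][r, c] = fwhm
            images["fraction_zea"][r, c] = corrected
            images["raw_fraction_zea"][r, c] = raw

    frac_failed = failed.mean()
    if frac_failed > failure_threshold:
        raise NumericalError(
            f"{frac_failed:.1%} of pixels failed to fit "
            f"(threshold {failure_threshold:.0%})",
            diagnostics={"n_failed": int(failed.sum())},
        )
    return PigmentMap(
        plane=smap.plane,
        pixel_size_um=smap.pixel_size_um,
        images=images,
        failed=failed,
        laser_nm=smap.laser_nm,
        metadata={"estimator": estimator, "calibrated": calibration is not None},
    )


def find_center(pmap: PigmentMap, percentile: float = 95.0) -> tuple[float, float]:
    """Intensity-weighted centroid of the brightest pixels of the total image.

    Pixels above the given percentile of total concentration contribute
    with their intensity as weight; returns (x, y) in µm.
    """
    total = pmap.images["total"]
    valid = ~pmap.failed & np.isfinite(total)
    vals = total[valid]
    if vals.size == 0 or np.ptp(vals) == 0:
        raise DataError("total image is constant or empty: center undefined")
    thresh = np.percentile(vals, percentile)
    sel = valid & (total >= thresh)
    xx, yy = pmap.coordinate_grids_um()
    w = total[sel]
    return (float(np.sum(xx[sel] * w) / w.sum()), float(np.sum(yy[sel] * w) / w.sum()))


def radial_profile(
    pmap: PigmentMap,
    center_um: tuple[float, float] | None = None,
    bin_width_um: float = 10.0,
) -> RadialProfile:
    """Annulus-averaged means and SDs of every image vs radius from center."""
    if bin_width_um <= 0:
        raise DataError("bin_width_um must be > 0")
    if center_um is None:
        center_um = find_center(pmap)
    xx, yy = pmap.coordinate_grids_um()
    cx, cy = center_um
    if not (xx.min() - 1 <= cx <= xx.max() + 1 and yy.min() - 1 <= cy <= yy.max() + 1):
        raise DataError(f"center {center_um} µm lies outside the map")
    rr = np.hypot(xx - cx, yy - cy)
    valid = ~pmap.failed
    n_bins = int(np.ceil(rr[valid].max() / bin_width_um)) + 1
    idx = np.minimum((rr / bin_width_um).astype(int), n_bins - 1)

    n = np.bincount(idx[valid], minlength=n_bins)
    mean, sd = {}, {}
    for name, img in pmap.images.items():
        ok = valid & np.isfinite(img)
        cnt = np.bincount(idx[ok], minlength=n_bins)
        s1 = np.bincount(idx[ok], weights=img[ok], minlength=n_bins)
        s2 = np.bincount(idx[ok], weights=img[ok] ** 2, minlength=n_bins)
        with np.errstate(divide="ignore", invalid="ignore"):
            m = s1 / cnt
            var = np.maximum(s2 / cnt - m**2, 0.0)
        mean[name] = m
        sd[name] = np.sqrt(var)
    radius = (np.arange(n_bins) + 0.5) * bin_width_um
    return RadialProfile(
        radius_um=radius, bin_width_um=bin_width_um, n=n, mean=mean, sd=sd
    )


def _three_tap_smooth(y: np.ndarray) -> np.ndarray:
    """3-tap discrete Gaussian [0.25, 0.5, 0.25] with edge replication."""
    padded = np.concatenate([y[:1], y, y[-1:]])
    return 0.25 * padded[:-2] + 0.5 * padded[1:-1] + 0.25 * padded[2:]


def segment_regions(
    pmap: PigmentMap,
    center_um: tuple[float, float] | None = None,
    mode: str = "fixed",
    fixed_diameters_mm: tuple[float, float, float] = DEFAULT_REGION_DIAMETERS_MM,
    profile: RadialProfile | None = None,
) -> RegionSegmentation:
    """Label pixels foveola / fovea / parafovea / outside around the center.

    ``fixed`` mode thresholds the radius at the anatomical diameters
    (defaults 0.35 / 1 / 2 mm).  ``data_driven`` mode finds the three
    largest-magnitude local minima of the second difference of the
    smoothed log radial total-concentration profile (the marked changes in
    the concentration profile), sorts them by radius and uses them as the
    boundary radii; the innermost is the foveola boundary.
    """
    if center_um is None:
        center_um = find_center(pmap)
    if mode == "fixed":
        d1, d2, d3 = fixed_diameters_mm
        if not 0 < d1 < d2 < d3:
            raise DataError("fixed diameters must be strictly increasing")
        radii = (d1 * 500.0, d2 * 500.0, d3 * 500.0)
    elif mode == "data_driven":
        if profile is None:
            profile = radial_profile(pmap, center_um)
        total = profile.mean["total"]
        ok = np.isfinite(total) & (total > 0)
        r = profile.radius_um[ok]
        logt = np.log(total[ok])
        if r.size < 7:
            raise DataError("radial profile too short for data-driven segmentation")
        if np.ptp(logt) < 1e-6:
            raise DataError("flat concentration profile: no region boundaries to find")
        smooth = _three_tap_smooth(logt)
        curv = np.zeros_like(smooth)
        curv[1:-1] = smooth[:-2] - 2.0 * smooth[1:-1] + smooth[2:]
        # local minima of the curvature
        minima = [
            i
            for i in range(1, curv.size - 1)
            if curv[i] < 0 and curv[i] <= curv[i - 1] and curv[i] <= curv[i + 1]
        ]
        if len(minima) < 3:
            raise DataError(
                f"found only {len(minima)} concentration-profile shoulders; "
                "cannot place three region boundaries"
            )
        strongest = sorted(minima, key=lambda i: curv[i])[:3]
        boundaries = []
        for i in sorted(strongest):
            # parabolic sub-bin refinement of the minimum position
            denom = curv[i - 1] - 2.0 * curv[i] + curv[i + 1]
            shift = 0.5 * (curv[i - 1] - curv[i + 1]) / denom if denom != 0 else 0.0
            boundaries.append(float(np.interp(i + shift, np.arange(r.size), r)))
        radii = tuple(boundaries)
    else:
        raise DataError(f"unknown segmentation mode {mode!r}")

    xx, yy = pmap.coordinate_grids_um()
    rr = np.hypot(xx - center_um[0], yy - center_um[1])
    labels = np.digitize(rr, radii)  # 0..3
    return RegionSegmentation(
        center_um=center_um,
        boundary_radii_um=radii,
        labels=labels,
        method=mode,
    )


def region_ratios(
    pmap: PigmentMap, segmentation: RegionSegmentation
) -> dict[str, dict[str, float] | None]:
    """Per-region Zea:Lut ratio (ratio of regional means), SD, n, mean total.

    The ratio is computed as mean(zea)/mean(lut) per region rather than the
    mean of per-pixel ratios, which noise-amplified division would distort.
    Regions without unmasked pixels are reported as None (missing).
    """
    if segmentation.labels.shape != pmap.shape:
        raise DataError("segmentation grid does not match the pigment map")
    out: dict[str, dict[str, float] | None] = {}
    lut, zea, total = (pmap.images[k] for k in ("lut", "zea", "total"))
    for k, name in enumerate(REGION_NAMES):
        sel = (segmentation.labels == k) & ~pmap.failed & np.isfinite(lut)
        n = int(sel.sum())
        if n == 0:
            out[name] = None
            continue
        mean_lut = float(lut[sel].mean())
        mean_zea = float(zea[sel].mean())
        with np.errstate(divide="ignore", invalid="ignore"):
            pixel_ratio = zea[sel] / lut[sel]
        pixel_ratio = pixel_ratio[np.isfinite(pixel_ratio)]
        out[name] = {
            "ratio": mean_zea / mean_lut if mean_lut > 0 else np.inf,
            "ratio_sd": float(np.std(pixel_ratio, ddof=1)) if pixel_ratio.size > 1 else 0.0,
            "n": n,
            "mean_total": float(total[sel].mean()),
            "mean_lut": mean_lut,
            "mean_zea": mean_zea,
        }
    return out


def line_cross_section(
    pmap: PigmentMap,
    start_um: tuple[float, float],
    end_um: tuple[float, float],
    width_px: int = 1,
) -> dict[str, np.ndarray]:
    """Perpendicular-averaged image profiles along a line segment.

    Samples at pixel-pitch steps from ``start_um`` to ``end_um`` (µm
    coordinates), averaging ``width_px`` nearest-pixel rows perpendicular
    to the segment.  Returns ``{"distance_um": ..., <image>: ...}``.
    """
    start = np.asarray(start_um, float)
    end = np.asarray(end_um, float)
    length = float(np.linalg.norm(end - start))
    if length == 0:
        raise DataError("zero-length cross-section segment")
    xx, yy = pmap.coordinate_grids_um()
    for pt in (start, end):
        if not (xx.min() - 1 <= pt[0] <= xx.max() + 1 and yy.min() - 1 <= pt[1] <= yy.max() + 1):
            raise DataError(f"cross-section endpoint {tuple(pt)} outside the map")
    if width_px < 1:
        raise DataError("width_px must be >= 1")
    pitch = float(min(pmap.pixel_size_um))
    u = (end - start) / length
    nvec = np.array([-u[1], u[0]])
    distances = np.arange(0.0, length + pitch / 2, pitch)
    offsets = (np.arange(width_px) - (width_px - 1) / 2.0) * pitch

    pr, pc = pmap.pixel_size_um
    n_rows, n_cols = pmap.shape
    out = {"distance_um": distances}
    for name, img in pmap.images.items():
        vals = np.full((distances.size, width_px), np.nan)
        for j, off in enumerate(offsets):
            pts = start[None, :] + distances[:, None] * u[None, :] + off * nvec[None, :]
            cols = np.clip((pts[:, 0] / pc - 0.5).round().astype(int), 0, n_cols - 1)
            rows = np.clip((pts[:, 1] / pr - 0.5).round().astype(int), 0, n_rows - 1)
            v = img[rows, cols].copy()
            v[pmap.failed[rows, cols]] = np.nan
            vals[:, j] = v
        with np.errstate(invalid="ignore"):
            out[name] = np.nanmean(vals, axis=1)
    return out


def _profile_peak_and_fwhm(z_um: np.ndarray, profile: np.ndarray) -> tuple[float, float]:
    """Peak position (parabolic sub-bin) and FWHM (interpolated crossings)."""
    i = int(np.nanargmax(profile))
    peak = z_um[i]
    if 0 < i < profile.size - 1:
        denom = profile[i - 1] - 2.0 * profile[i] + profile[i + 1]
        if denom != 0:
            shift = 0.5 * (profile[i - 1] - profile[i + 1]) / denom
            peak = float(np.interp(i + shift, np.arange(z_um.size), z_um))
    half = profile[i] / 2.0
    left = right = np.nan
    for j in range(i, 0, -1):
        if profile[j - 1] <= half:
            left = np.interp(half, [profile[j - 1], profile[j]], [z_um[j - 1], z_um[j]])
            break
    for j in range(i, profile.size - 1):
        if profile[j + 1] <= half:
            right = np.interp(half, [profile[j + 1], profile[j]], [z_um[j + 1], z_um[j]])
            break
    return float(peak), float(right - left)


def zscan_profile(
    smap: SpectralMap,
    estimator_config: dict | None = None,
    calibration: CalibrationCurve | None = None,
) -> dict[str, Any]:
    """Depth profiles of lutein and zeaxanthin from an XZ scan.

    Runs :func:`map_pixelwise` on the XZ map, averages each concentration
    image over X, and reports each pigment's layer peak depth and FWHM.
    """
    if smap.plane != "XZ":
        raise DataError("zscan_profile expects an XZ map")
    pmap = map_pixelwise(smap, estimator_config, calibration)
    z_um = pmap.pixel_centers_um()[0]
    out: dict[str, Any] = {"z_um": z_um}
    for name in ("lut", "zea", "total"):
        img = np.where(pmap.failed, np.nan, pmap.images[name])
        with np.errstate(invalid="ignore"):
            prof = np.nanmean(img, axis=1)
        prof = np.nan_to_num(prof, nan=0.0)
        out[name] = prof
        peak, fwhm = _profile_peak_and_fwhm(z_um, prof)
        out[f"{name}_peak_um"] = peak
        out[f"{name}_fwhm_um"] = fwhm
    return out
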