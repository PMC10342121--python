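"""nu1-band analysis: location, FWHM, two-Gaussian deconvolution, fractions.

The nu1 (C=C stretch) band of a lutein/zeaxanthin mixture is a sum of two
Gaussians centered near 1526 and 1521 cm^-1.  The band is located within
the 1480-1580 cm^-1 search range, its observed FWHM measured by linear
interpolation of the half-maximum crossings, and the two-component model
fitted by bounded nonlinear least squares.  Component amplitudes are
solved linearly (non-negative least squares) inside the residual, so the
nonlinear search runs over centers and widths only; a deterministic grid
of width starts makes the fit reproducible without any random state.

Pigment fractions derive from component AREAS (area = amplitude * sigma *
sqrt(2 pi)), the physically meaningful proxy for concentration, and can
be corrected for the relative resonance cross-sections s(p, L).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls

from .basis import FWHM_TO_SIGMA, NU1_CENTER
from .errors import DataError, NumericalError
from .spectra import RamanSpectrum

__all__ = [
    "Nu1Fit",
    "locate_nu1",
    "measure_nu1_fwhm",
    "fit_nu1_gaussians",
    "fractions_from_areas",
]

NU1_SEARCH = (1480.0, 1580.0)
DEFAULT_HALF_WINDOW = 40.0
DEFAULT_CENTER_SLACK = 3.0
DEFAULT_FWHM_BOUNDS = (5.0, 40.0)
DEFAULT_WIDTH_STARTS = (10.0, 14.0, 20.0)

SQRT_2PI = np.sqrt(2.0 * np.pi)


@dataclass
class Nu1Fit:
    """Result of the two-Gaussian nu1 deconvolution of one spectrum."""

    center_lut: float
    center_zea: float
    fwhm_lut: float
    fwhm_zea: float
    area_lut: float
    area_zea: float
    raw_fraction_zea: float
    corrected_fraction_zea: float
    observed_band_fwhm: float
    goodness: float
    residual: np.ndarray = field(repr=False)

    @property
    def raw_fraction_lut(self) -> float:
        return 1.0 - self.raw_fraction_zea


def locate_nu1(
    spectrum: RamanSpectrum,
    search: tuple[float, float] = NU1_SEARCH,
    half_window: float = DEFAULT_HALF_WINDOW,
) -> tuple[float, float]:
    """Window (cm^-1 interval) around the nu1 intensity maximum.

    Searches [1480, 1580] by default and returns a symmetric window of
    +-``half_window`` around the maximum, clipped to the spectrum axis.
    """
    nu, y = spectrum.wavenumbers, spectrum.intensity
    mask = (nu >= search[0]) & (nu <= search[1])
    if mask.sum() < 3:
        raise DataError(f"spectrum does not cover the nu1 search range {search}")
    ys = y[mask]
    if np.ptp(ys) == 0:
        raise DataError("flat spectrum in the nu1 search range: no band to locate")
    i = int(np.argmax(ys))
    if i == 0 or i == ys.size - 1:
        raise DataError("nu1 maximum lies on the edge of the search range")
    center = float(nu[mask][i])
    return (max(center - half_window, nu[0]), min(center + half_window, nu[-1]))


def measure_nu1_fwhm(
    spectrum: RamanSpectrum, window: tuple[float, float] | None = None
) -> float:
    """Observed FWHM of the nu1 band, by interpolated half-maximum crossings.

    The baseline inside the window is assumed to be zero (preprocessed
    input); the band maximum must lie strictly inside the window.
    """
    if window is None:
        window = locate_nu1(spectrum)
    nu, y = spectrum.wavenumbers, spectrum.intensity
    mask = (nu >= window[0]) & (nu <= window[1])
    x, v = nu[mask], y[mask]
    if x.size < 3:
        raise DataError("window too narrow to measure a width")
    i_max = int(np.argmax(v))
    if i_max in (0, v.size - 1):
        raise DataError("band maximum is not strictly inside the window")
    half = v[i_max] / 2.0

    def _cross(indices) -> float:
        # walk from the peak outward until the trace falls below half-max
        prev = i_max
        for j in indices:
            if v[j] <= half:
                # linear interpolation between bins j and prev
                x0, x1, y0, y1 = x[j], x[prev], v[j], v[prev]
                return x0 + (half - y0) * (x1 - x0) / (y1 - y0)
            prev = j
        raise DataError("half maximum not crossed inside the window")

    left = _cross(range(i_max - 1, -1, -1))
    right = _cross(range(i_max + 1, v.size))
    return float(right - left)


def _gaussian_design(nu, c_l, c_z, w_l, w_z) -> np.ndarray:
    sig_l, sig_z = w_l * FWHM_TO_SIGMA, w_z * FWHM_TO_SIGMA
    g = np.empty((nu.size, 2))
    g[:, 0] = np.exp(-((nu - c_l) ** 2) / (2.0 * sig_l**2))
    g[:, 1] = np.exp(-((nu - c_z) ** 2) / (2.0 * sig_z**2))
    return g


def fit_nu1_gaussians(
    spectrum: RamanSpectrum,
    window: tuple[float, float] | None = None,
    constraints: dict | None = None,
    cross_sections: tuple[float, float] = (1.0, 1.0),
) -> Nu1Fit:
    """Two-Gaussian fit of the nu1 band: A_l G(nu; c_l, s_l) + A_z G(nu; c_z, s_z).

    ``constraints`` keys (all optional): ``center_lut`` / ``center_zea``
    ((lo, hi) bounds, defaults 1526 +- 3 and 1521 +- 3 cm^-1),
    ``fwhm_bounds`` ((lo, hi), default (5, 40) cm^-1), ``width_starts``
    (deterministic start grid for both widths), ``fix_centers`` (bool:
    pin the centers at the bound midpoints), ``local_offset`` (bool: add a
    free flat baseline term inside the window, absorbing small residual
    baseline errors left by preprocessing).  Amplitudes are >= 0 by
    construction (non-negative least squares).  ``cross_sections`` is
    (s_lut, s_zea) used for the corrected fraction.
    """
    constraints = dict(constraints or {})
    if window is None:
        window = locate_nu1(spectrum)
    nu_all, y_all = spectrum.wavenumbers, spectrum.intensity
    mask = (nu_all >= window[0]) & (nu_all <= window[1])
    nu, y = nu_all[mask], y_all[mask]
    if nu.size < 6:
        raise DataError("nu1 window contains too few bins for a two-Gaussian fit")

    cl_lo, cl_hi = constraints.get(
        "center_lut", (NU1_CENTER["lut"] - DEFAULT_CENTER_SLACK, NU1_CENTER["lut"] + DEFAULT_CENTER_SLACK)
    )
    cz_lo, cz_hi = constraints.get(
        "center_zea", (NU1_CENTER["zea"] - DEFAULT_CENTER_SLACK, NU1_CENTER["zea"] + DEFAULT_CENTER_SLACK)
    )
    w_lo, w_hi = constraints.get("fwhm_bounds", DEFAULT_FWHM_BOUNDS)
    width_starts = tuple(constraints.get("width_starts", DEFAULT_WIDTH_STARTS))
    fix_centers = bool(constraints.get("fix_centers", False))
    local_offset = bool(constraints.get("local_offset", False))

    c_l0 = np.clip(NU1_CENTER["lut"], cl_lo, cl_hi)
    c_z0 = np.clip(NU1_CENTER["zea"], cz_lo, cz_hi)

    if fix_centers:
        # centers pinned at the bound midpoints: optimize the two widths only
        c_l0, c_z0 = (cl_lo + cl_hi) / 2.0, (cz_lo + cz_hi) / 2.0

        def full_params(p):
            return (c_l0, c_z0, p[0], p[1])

        lower, upper = [w_lo, w_lo], [w_hi, w_hi]

        def start(w_l, w_z):
            return [w_l, w_z]

    else:

        def full_params(p):
            return tuple(p)

        lower = [cl_lo, cz_lo, w_lo, w_lo]
        upper = [cl_hi, cz_hi, w_hi, w_hi]

        def start(w_l, w_z):
            return [c_l0, c_z0, w_l, w_z]

    ones = np.ones((nu.size, 1))

    def _design(p):
        g = _gaussian_design(nu, *full_params(p))
        if local_offset:
            # sign-split offset columns keep the solve non-negative while
            # allowing a flat baseline term of either sign
            g = np.hstack([g, ones, -ones])
        return g

    def residual(p):
        g = _design(p)
        amps, _ = nnls(g, y)
        return g @ amps - y

    best = None
    for w_l0 in width_starts:
        for w_z0 in width_starts:
            p0 = start(np.clip(w_l0, w_lo, w_hi), np.clip(w_z0, w_lo, w_hi))
            try:
                sol = least_squares(
                    residual, p0, bounds=(lower, upper), method="trf", xtol=1e-12, ftol=1e-12
                )
            except Exception:
                continue
            if not sol.success:
                continue
            sse = float(sol.cost)
            amps, _ = nnls(_design(sol.x), y)
            # ties broken by the smaller zeaxanthin amplitude
            key = (round(sse, 12), amps[1])
            if best is None or key < best[0]:
                best = (key, sol, amps)
    if best is None:
        raise NumericalError(
            "nu1 two-Gaussian fit failed from every start",
            diagnostics={"window": window, "width_starts": width_starts},
        )
    _, sol, amps = best
    c_l, c_z, w_l, w_z = full_params(sol.x)
    a_l, a_z = amps[0], amps[1]
    area_l = a_l * w_l * FWHM_TO_SIGMA * SQRT_2PI
    area_z = a_z * w_z * FWHM_TO_SIGMA * SQRT_2PI
    raw, corrected = fractions_from_areas(area_l, area_z, *cross_sections)

    resid = sol.fun
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    goodness = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else -np.inf
    return Nu1Fit(
        center_lut=float(c_l),
        center_zea=float(c_z),
        fwhm_lut=float(w_l),
        fwhm_zea=float(w_z),
        area_lut=float(area_l),
        area_zea=float(area_z),
        raw_fraction_zea=raw,
        corrected_fraction_zea=corrected,
        observed_band_fwhm=measure_nu1_fwhm(spectrum, window),
        goodness=goodness,
        residual=resid,
    )


def fractions_from_areas(
    area_lut: float, area_zea: float, s_lut: float = 1.0, s_zea: float = 1.0
) -> tuple[float, float]:
    """(raw, cross-section-corrected) zeaxanthin fraction from component areas.

    raw = A_z / (A_z + A_l);
    corrected = (A_z/s_z) / (A_z/s_z + A_l/s_l), which undoes the resonance
    weighting when the relative cross-sections are known.
    """
    if area_lut < 0 or area_zea < 0:
        raise DataError("component areas must be >= 0")
    if s_lut <= 0 or s_zea <= 0:
        raise DataError("cross-sections must be > 0")
    total = area_lut + area_zea
    if total == 0:
        raise DataError("both component areas are zero: fraction undefined")
    raw = area_zea / total
    cz, cl = area_zea / s_zea, area_lut / s_lut
    corrected = cz / (cz + cl)
    return float(raw), float(corrected)
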