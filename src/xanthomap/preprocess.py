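"""Spectral pre-processing: cosmic-ray removal, baseline correction, cropping.

Cosmic rays are detected as outliers of the modified z-score of the second
difference (Whitaker-Hayes style) and replaced by the local median of
unflagged neighbors.  Baseline estimation uses asymmetric penalized least
squares (AsLS) by default, with an iteratively reweighted polynomial
alternative.  Cropping restricts the axis to the analysis window,
800-1800 cm^-1 by default.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.linalg import solveh_banded

from .errors import DataError, NumericalError
from .spectra import RamanSpectrum, SpectralMap

__all__ = [
    "modified_zscores",
    "remove_cosmic_rays",
    "correct_baseline",
    "crop_region",
    "preprocess_spectrum",
    "preprocess_map",
]


def modified_zscores(values: np.ndarray, scale_floor: float = 0.0) -> np.ndarray:
    """Modified z-score 0.6745 (x - median) / MAD, robust to outliers.

    ``scale_floor`` puts a lower bound on the MAD scale; spike detection
    uses a floor proportional to the band peak height so that smooth band
    curvature is never mistaken for a spike, whatever the signal-to-noise
    ratio (a cosmic ray is tens of times the band peak, band curvature at
    most a twentieth of it).
    """
    v = np.asarray(values, dtype=float)
    med = np.median(v)
    mad = max(np.median(np.abs(v - med)), scale_floor)
    if mad == 0:
        # all-equal values and no floor: nothing is an outlier
        return np.zeros_like(v)
    return 0.6745 * (v - med) / mad


def remove_cosmic_rays(
    spectrum: RamanSpectrum, z_threshold: float = 8.0, window: int = 5
) -> RamanSpectrum:
    """Replace single-bin spikes by the local median of unflagged neighbors.

    A bin is flagged when the modified z-score of the second difference of
    the intensity trace exceeds ``z_threshold`` in absolute value; the MAD
    scale of the score is floored at 1/20 of the (median-filtered) signal
    range so that band curvature is not spike-like at high SNR; flagged
    bins are replaced by the local median of unflagged neighbors inside
    ``window``.  All unflagged bins are returned bit-exactly; the flagged
    indices are recorded in ``metadata["cosmic_ray_bins"]``.
    """
    if z_threshold <= 0:
        raise DataError(f"z_threshold must be > 0, got {z_threshold}")
    if window < 3 or window % 2 == 0:
        raise DataError(f"window must be odd and >= 3, got {window}")
    y = spectrum.intensity
    if y.size < window:
        raise DataError(
            f"spectrum of {y.size} bins shorter than window {window}"
        )
    from scipy.ndimage import median_filter

    # curvature guard: the largest second difference a smooth band can
    # produce is well under 1/20 of its despiked peak-to-baseline range
    signal_range = float(np.ptp(median_filter(y, size=window, mode="nearest")))
    floor = signal_range / 20.0

    def _zscores(trace):
        d2 = np.zeros_like(trace)
        d2[1:-1] = trace[:-2] - 2.0 * trace[1:-1] + trace[2:]
        return modified_zscores(d2, scale_floor=floor)

    z = _zscores(y)
    # a spike at bin i also perturbs d2 at i-1 and i+1; candidates are all
    # threshold crossings, but flags are restricted to local |z| extrema so
    # a spike's innocent neighbors are left untouched
    candidates = np.abs(z) > z_threshold
    cleaned = y.copy()
    flagged = np.zeros_like(candidates)
    half = window // 2

    def _replace(i):
        # exclude already-flagged bins and immediately adjacent candidates
        # (a shadowed twin spike) from the replacement median
        span = half
        while True:
            lo, hi = max(i - span, 0), min(i + span + 1, y.size)
            neighbors = [
                j
                for j in range(lo, hi)
                if not flagged[j] and not (candidates[j] and abs(j - i) <= 1)
            ]
            if neighbors or (lo == 0 and hi == y.size):
                break
            span += 1
        if neighbors:
            cleaned[i] = np.median(cleaned[neighbors])

    # adjacent spikes shadow each other's |z| extremum: iterate, but only
    # ever flag first-pass candidates, so smooth band curvature exposed by a
    # shrinking MAD can never start a cascade
    for _ in range(5):
        new = []
        for i in np.nonzero(candidates & ~flagged)[0]:
            lo, hi = max(i - 1, 0), min(i + 2, y.size)
            if np.abs(z[i]) >= np.abs(z[lo:hi]).max():
                new.append(i)
        if not new:
            break
        for i in new:
            flagged[i] = True
            _replace(i)
        z = _zscores(cleaned)
        candidates &= np.abs(z) > z_threshold
    return spectrum.copy(
        intensity=cleaned, cosmic_ray_bins=np.nonzero(flagged)[0].tolist()
    )


def _asls_baseline(
    y: np.ndarray, lam: float, p: float, max_iter: int = 50, tol: float = 1e-6
) -> np.ndarray:
    """Asymmetric penalized least-squares baseline (Eilers-Boelens style).

    The pentadiagonal system (W + lam D'D) b = W y is solved with a banded
    Cholesky factorization, which keeps per-spectrum cost low enough for
    pixel-wise map preprocessing.
    """
    n = y.size
    d = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    penalty = (lam * (d.T @ d)).todia()
    # lower-banded representation: ab[i, j] = A[j + i, j]
    ab0 = np.zeros((3, n))
    for off in (0, -1, -2):
        diag = penalty.diagonal(off)
        ab0[-off, : diag.size] = diag
    w = np.ones(n)
    baseline = y
    for _ in range(max_iter):
        ab = ab0.copy()
        ab[0] += w
        baseline = solveh_banded(ab, w * y, lower=True)
        w_new = np.where(y > baseline, p, 1.0 - p)
        if np.allclose(w_new, w, atol=tol):
            return baseline
        w = w_new
    raise NumericalError(
        "AsLS baseline did not converge",
        diagnostics={"max_iter": max_iter, "lam": lam, "p": p},
    )


def _polynomial_baseline(
    y: np.ndarray, x: np.ndarray, degree: int, max_iter: int = 50, tol: float = 1e-8
) -> np.ndarray:
    """Iterative polynomial baseline: refit after clipping points above the fit."""
    target = y.copy()
    xs = (x - x.mean()) / (x.max() - x.min())
    baseline = np.zeros_like(y)
    for _ in range(max_iter):
        coef = np.polynomial.polynomial.polyfit(xs, target, degree)
        baseline = np.polynomial.polynomial.polyval(xs, coef)
        clipped = np.minimum(target, baseline)
        if np.max(np.abs(clipped - target)) < tol * max(np.max(np.abs(y)), 1.0):
            return baseline
        target = clipped
    return baseline


def correct_baseline(
    spectrum: RamanSpectrum,
    method: str = "asymmetric_penalized",
    params: dict | None = None,
) -> RamanSpectrum:
    """Subtract an estimated baseline; the estimate is kept in metadata.

    ``asymmetric_penalized`` (default): AsLS with smoothness ``lam``
    (default 1e7) and asymmetry ``p`` (default 1e-3).  ``polynomial``:
    iteratively clipped polynomial of ``degree`` <= 5 (default 3).
    """
    params = dict(params or {})
    y = spectrum.intensity
    if method == "asymmetric_penalized":
        lam = float(params.pop("lam", 1e7))
        p = float(params.pop("p", 1e-3))
        if lam <= 0 or not 0 < p < 1:
            raise DataError("AsLS needs lam > 0 and 0 < p < 1")
        baseline = _asls_baseline(y, lam, p, **params)
    elif method == "polynomial":
        degree = int(params.pop("degree", 3))
        if degree > 5 or degree < 0:
            raise DataError(f"polynomial degree must be in 0..5, got {degree}")
        baseline = _polynomial_baseline(y, spectrum.wavenumbers, degree, **params)
    else:
        raise DataError(f"unknown baseline method {method!r}")
    return spectrum.copy(
        intensity=y - baseline,
        baseline=baseline,
        baseline_method=method,
    )


def crop_region(
    spectrum: RamanSpectrum, lo_cm1: float = 800.0, hi_cm1: float = 1800.0
) -> RamanSpectrum:
    """Retain the bins with wavenumber in [lo, hi] inclusive."""
    if lo_cm1 >= hi_cm1:
        raise DataError(f"crop bounds must satisfy lo < hi, got {lo_cm1} >= {hi_cm1}")
    mask = (spectrum.wavenumbers >= lo_cm1) & (spectrum.wavenumbers <= hi_cm1)
    if not np.any(mask):
        raise DataError(
            f"crop window [{lo_cm1}, {hi_cm1}] does not overlap the axis "
            f"[{spectrum.wavenumbers[0]}, {spectrum.wavenumbers[-1]}]"
        )
    meta = dict(spectrum.metadata)
    meta["crop"] = (lo_cm1, hi_cm1)
    return RamanSpectrum(
        spectrum.wavenumbers[mask].copy(),
        spectrum.intensity[mask].copy(),
        spectrum.laser_nm,
        meta,
    )


def preprocess_spectrum(
    spectrum: RamanSpectrum, config: dict | None = None
) -> RamanSpectrum:
    """Full chain: cosmic-ray removal -> baseline correction -> crop.

    ``config`` keys: ``z_threshold``, ``window``, ``baseline`` (dict with
    ``method`` and method params), ``crop`` ((lo, hi) or None to skip).
    """
    config = dict(config or {})
    out = remove_cosmic_rays(
        spectrum,
        z_threshold=config.get("z_threshold", 8.0),
        window=config.get("window", 5),
    )
    baseline_cfg = dict(config.get("baseline", {}))
    method = baseline_cfg.pop("method", "asymmetric_penalized")
    out = correct_baseline(out, method=method, params=baseline_cfg)
    crop = config.get("crop", (800.0, 1800.0))
    if crop is not None:
        out = crop_region(out, *crop)
    return out


def preprocess_map(smap: SpectralMap, config: dict | None = None) -> SpectralMap:
    """Apply :func:`preprocess_spectrum` pixel-wise with one shared config."""
    n_rows, n_cols = smap.shape
    first = preprocess_spectrum(smap.pixel(0, 0), config)
    out = np.empty((n_rows, n_cols, first.n_bins))
    out[0, 0] = first.intensity
    for r in range(n_rows):
        for c in range(n_cols):
            if r == 0 and c == 0:
                continue
            out[r, c] = preprocess_spectrum(smap.pixel(r, c), config).intensity
    meta = dict(smap.metadata)
    meta["preprocessed"] = True
    return SpectralMap(
        plane=smap.plane,
        wavenumbers=first.wavenumbers,
        intensity=out,
        pixel_size_um=smap.pixel_size_um,
        laser_nm=smap.laser_nm,
        metadata=meta,
    )
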