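"""Polarized TCSPC analysis: lifetime fits, anisotropy, sector statistics.

Decays are tail-fitted (no IRF deconvolution; the fit window starts two
bins after the histogram peak) with a one- or two-exponential model under
Poisson maximum likelihood.  The short-lifetime fraction is the
PRE-EXPONENTIAL (amplitude) fraction, proportional to the emitter
population.  Fluorescence anisotropy follows

    r = (I_par - G I_perp) / (I_par + 2 G I_perp)

with the instrumental G factor as an input.  Sector statistics quantify
the photoselection pattern of axon cross-sections (bright left/right vs
dim top/bottom sectors for transmembrane, radially oriented dipoles under
horizontal excitation polarization), and the power trend tests whether
the short-lifetime fraction depends on the scanning laser power.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize

from .errors import DataError, NumericalError
from .flimdata import DecayHistogram, FLIMDataset

__all__ = [
    "BiexpFit",
    "AnisotropyResult",
    "fit_decay",
    "short_fraction",
    "anisotropy",
    "sector_statistics",
    "short_fraction_series",
    "power_trend",
]


@dataclass
class BiexpFit:
    """Exponential-decay fit parameters (components ordered short < long).

    ``amp_short`` / ``amp_long`` are continuous pre-exponential amplitudes
    (counts per ps at t = window start); ``f_short`` is the amplitude
    fraction amp_short / (amp_short + amp_long).
    """

    tau_short_ps: float
    tau_long_ps: float
    amp_short: float
    amp_long: float
    f_short: float
    background: float
    deviance: float
    n_components: int
    converged: bool
    degenerate: bool = False
    fisher_se_f_short: float = np.nan
    window_bins: tuple[int, int] = (0, 0)

    @property
    def tau_ps(self) -> float:
        """Dominant lifetime (the only one for a single-component fit)."""
        return self.tau_long_ps


def _model_bin_counts(time_edges, amps, taus, bg):
    """Expected counts per bin: sum_p amp_p * tau_p * (e^-t0/tau - e^-t1/tau) + bg."""
    lam = np.full(time_edges.size - 1, bg, dtype=float)
    for a, tau in zip(amps, taus):
        lam += a * tau * (np.exp(-time_edges[:-1] / tau) - np.exp(-time_edges[1:] / tau))
    return lam


def _poisson_nll(lam, counts):
    lam = np.clip(lam, 1e-300, None)
    return float(np.sum(lam) - np.sum(counts * np.log(lam)))


def _tail_slope_init(t, y, n_components):
    """Deterministic initialization from log-linear tail slopes."""
    pos = y > 0
    if pos.sum() < 4:
        raise NumericalError("too few populated bins for initialization")
    # long component from the late half of the populated range
    late = pos & (t >= np.median(t[pos]))
    coef_l = np.polyfit(t[late], np.log(y[late]), 1)
    tau_l = -1.0 / min(coef_l[0], -1e-9)
    amp_l = np.exp(coef_l[1])
    if n_components == 1:
        return [amp_l], [tau_l]
    resid = y - amp_l * np.exp(-t / tau_l)
    early = pos & (t <= np.quantile(t[pos], 0.1)) & (resid > 0)
    if early.sum() >= 2:
        coef_s = np.polyfit(t[early], np.log(resid[early]), 1)
        tau_s = -1.0 / min(coef_s[0], -1e-9)
        amp_s = np.exp(coef_s[1])
    else:  # no early excess: start from a nominal fast component
        tau_s, amp_s = tau_l / 20.0, y.max() * 0.1
    tau_s = float(np.clip(tau_s, 1.0, tau_l * 0.9))
    return [max(amp_s, 1e-6), amp_l], [tau_s, tau_l]


def _grid_init(edges, y, n_components, tau_anchor):
    """Deterministic coarse search over lifetime pairs around the tail anchor.

    For each candidate lifetime set, bin-integrated component shapes plus a
    flat background column are fitted by non-negative least squares; the
    candidate with the best Poisson likelihood seeds the MLE refinement.
    """
    from scipy.optimize import nnls as _nnls

    factors = np.array([0.25, 0.5, 1.0, 2.0])
    tau_l_grid = np.unique(np.clip(tau_anchor * factors, edges[1], 1e7))
    ratios = np.array([0.01, 0.03, 0.1, 0.3])
    best = None
    for tau_l in tau_l_grid:
        for rho in ratios if n_components == 2 else [None]:
            taus = [tau_l] if rho is None else [rho * tau_l, tau_l]
            cols = [tau * (np.exp(-edges[:-1] / tau) - np.exp(-edges[1:] / tau)) for tau in taus]
            cols.append(np.ones(edges.size - 1))
            design = np.column_stack(cols)
            coef, _ = _nnls(design, y)
            lam = design @ coef
            nll = _poisson_nll(lam, y)
            if best is None or nll < best[0]:
                best = (nll, np.maximum(coef[:-1], 1e-12), taus, coef[-1])
    _, amps, taus, bg = best
    return list(amps), list(taus), float(bg)


def fit_decay(
    histogram: DecayHistogram,
    n_components: int = 2,
    fit_window: tuple[int, int] | None = None,
    min_counts: int = 100,
) -> BiexpFit:
    """Poisson maximum-likelihood tail fit of a decay histogram.

    Fits the channel-summed histogram with
    ``sum_i a_i exp(-t/tau_i) + background`` integrated over bins.  The
    fit window defaults to (peak bin + 2, end).  Components are relabeled
    so tau_short < tau_long; lifetimes within 10 % of each other set the
    ``degenerate`` flag.  The standard error of f_short is estimated from
    the observed Fisher information (used by the power-trend analysis).
    """
    if n_components not in (1, 2):
        raise DataError("n_components must be 1 or 2")
    counts = histogram.counts_total.astype(float)
    if fit_window is None:
        start = int(np.argmax(counts)) + 2
        fit_window = (start, counts.size)
    lo, hi = fit_window
    if not (0 <= lo < hi <= counts.size):
        raise DataError(f"invalid fit window {fit_window}")
    y = counts[lo:hi]
    if y.sum() < min_counts:
        raise DataError(
            f"only {int(y.sum())} counts in the fit window (minimum {min_counts})"
        )
    bin_ps = histogram.bin_ps
    t0 = histogram.time_ps[lo:hi] - histogram.time_ps[lo]
    edges = np.append(t0, t0[-1] + bin_ps)
    t_centers = t0 + bin_ps / 2.0

    _, taus_anchor = _tail_slope_init(t_centers, y, 1)
    amps0, taus0, bg0 = _grid_init(edges, y, n_components, taus_anchor[0])

    def unpack(theta):
        amps = np.exp(theta[:n_components])
        taus = np.exp(theta[n_components : 2 * n_components])
        bg = theta[-1]
        return amps, taus, bg

    def nll(theta):
        amps, taus, bg = unpack(theta)
        return _poisson_nll(_model_bin_counts(edges, amps, taus, bg), y)

    theta0 = np.concatenate(
        [np.log(np.maximum(amps0, 1e-12)), np.log(taus0), [bg0]]
    )
    bounds = (
        [(-40.0, 40.0)] * n_components
        + [(np.log(bin_ps / 10.0), np.log(1e7))] * n_components
        + [(0.0, max(float(y.max()), 1.0))]
    )
    res = minimize(nll, theta0, method="L-BFGS-B", bounds=bounds)
    if not res.success and not np.isfinite(res.fun):
        raise NumericalError("decay fit did not converge", diagnostics={"message": res.message})
    amps, taus, bg = unpack(res.x)
    lam = _model_bin_counts(edges, amps, taus, bg)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_terms = lam - y + np.where(y > 0, y * np.log(y / np.clip(lam, 1e-300, None)), 0.0)
    deviance = float(2.0 * np.sum(dev_terms))

    if n_components == 1:
        return BiexpFit(
            tau_short_ps=float(taus[0]),
            tau_long_ps=float(taus[0]),
            amp_short=0.0,
            amp_long=float(amps[0]),
            f_short=0.0,
            background=float(bg),
            deviance=deviance,
            n_components=1,
            converged=bool(res.success),
            window_bins=fit_window,
        )

    order = np.argsort(taus)
    taus, amps = taus[order], amps[order]
    # amplitudes refer to the window start; extrapolate back to the decay
    # origin so f_short is the amplitude fraction of the full decay
    t_offset = float(histogram.time_ps[lo] - histogram.time_ps[0])
    amps = amps * np.exp(t_offset / taus)
    f_short = float(amps[0] / (amps[0] + amps[1]))
    degenerate = bool(taus[1] <= taus[0] * 1.1)
    se = _fisher_se_f_short(res.x[np.r_[order, order + 2, [4]]], edges, y, t_offset)
    return BiexpFit(
        tau_short_ps=float(taus[0]),
        tau_long_ps=float(taus[1]),
        amp_short=float(amps[0]),
        amp_long=float(amps[1]),
        f_short=f_short,
        background=float(bg),
        deviance=deviance,
        n_components=2,
        converged=bool(res.success),
        degenerate=degenerate,
        fisher_se_f_short=se,
        window_bins=fit_window,
    )


def _fisher_se_f_short(theta, edges, counts, t_offset=0.0, eps=1e-4):
    """Delta-method SE of f_short from the observed Fisher information.

    ``theta`` = (log a_s, log a_l, log tau_s, log tau_l, bg) at the optimum;
    ``t_offset`` is the window start relative to the decay origin, entering
    through the amplitude back-extrapolation exp(t_offset / tau).
    """
    def nll(th):
        amps = np.exp(th[:2])
        taus = np.exp(th[2:4])
        return _poisson_nll(_model_bin_counts(edges, amps, taus, th[4]), counts)

    k = theta.size
    hess = np.zeros((k, k))
    f0 = nll(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = eps
            ej = np.zeros(k); ej[j] = eps
            hess[i, j] = hess[j, i] = (
                nll(theta + ei + ej) - nll(theta + ei) - nll(theta + ej) + f0
            ) / eps**2
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return np.nan
    tau_s, tau_l = np.exp(theta[2]), np.exp(theta[3])
    a_s = np.exp(theta[0]) * np.exp(t_offset / tau_s)
    a_l = np.exp(theta[1]) * np.exp(t_offset / tau_l)
    f = a_s / (a_s + a_l)
    grad = np.zeros(k)
    grad[0] = f * (1 - f)
    grad[1] = -f * (1 - f)
    grad[2] = -f * (1 - f) * t_offset / tau_s  # d(t_off/tau)/d log tau = -t_off/tau
    grad[3] = f * (1 - f) * t_offset / tau_l
    var = float(grad @ cov @ grad)
    return float(np.sqrt(var)) if var > 0 else np.nan


def short_fraction(fit: BiexpFit) -> float:
    """Amplitude fraction of the short-lifetime component."""
    if fit.n_components != 2:
        raise DataError("short_fraction needs a two-component fit")
    if not fit.converged:
        raise DataError("short_fraction needs a converged fit")
    if fit.degenerate:
        import warnings

        warnings.warn(
            "lifetimes within 10%: short fraction is ill-defined", stacklevel=2
        )
    return fit.f_short


def anisotropy(i_parallel, i_perpendicular, g_factor: float = 1.0):
    """Fluorescence anisotropy r = (I_par - G I_perp) / (I_par + 2 G I_perp)."""
    if g_factor <= 0:
        raise DataError("g_factor must be > 0")
    ipar = np.asarray(i_parallel, dtype=float)
    iperp = np.asarray(i_perpendicular, dtype=float)
    if np.any(ipar < 0) or np.any(iperp < 0):
        raise DataError("intensities must be >= 0")
    denom = ipar + 2.0 * g_factor * iperp
    if np.isscalar(i_parallel) or ipar.ndim == 0:
        if denom == 0:
            raise DataError("zero total intensity: anisotropy undefined")
        return float((ipar - g_factor * iperp) / denom)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ipar - g_factor * iperp) / denom
    return np.where(denom > 0, r, np.nan)


@dataclass
class AnisotropyResult:
    """Anisotropy image plus sector summary of an annular ROI."""

    r_image: np.ndarray
    sector_intensity: dict[str, float]
    sector_r: dict[str, float]
    n_photons: int
    contrast_ratio: float  # pooled (left+right) / (top+bottom) intensity
    center_px: tuple[float, float]
    metadata: dict = field(default_factory=dict)


SECTORS = ("right", "top", "left", "bottom")


def sector_statistics(
    dataset: FLIMDataset,
    center_px: tuple[float, float] | None = None,
    inner_radius_px: float = 0.0,
    outer_radius_px: float | None = None,
    n_sectors: int = 4,
) -> AnisotropyResult:
    """Photon-weighted sector means of intensity and anisotropy on an annulus.

    Sectors are 90-degree wedges centered on the axes: right/left along
    +-x, top/bottom along +-y.  Sector anisotropy pools channel counts
    over the sector before applying the formula (photon weighting).  The
    contrast statistic is pooled (left+right) / (top+bottom) intensity.
    """
    if n_sectors != 4:
        raise DataError("sector analysis is defined for n_sectors = 4")
    ny, nx = dataset.shape
    if center_px is None:
        center_px = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    if outer_radius_px is None:
        outer_radius_px = min(nx, ny) / 2.0
    ipar, iperp = dataset.intensity_images()
    g = dataset.g_factor
    r_image = anisotropy(ipar, iperp, g)

    yy, xx = np.mgrid[0:ny, 0:nx]
    dx, dy = xx - center_px[0], yy - center_px[1]
    rr = np.hypot(dx, dy)
    ann = (rr >= inner_radius_px) & (rr <= outer_radius_px)
    angle = np.degrees(np.arctan2(dy, dx)) % 360.0

    wedges = {
        "right": (angle >= 315.0) | (angle < 45.0),
        "top": (angle >= 45.0) & (angle < 135.0),
        "left": (angle >= 135.0) & (angle < 225.0),
        "bottom": (angle >= 225.0) & (angle < 315.0),
    }
    total = ipar + iperp
    sector_intensity: dict[str, float] = {}
    sector_r: dict[str, float] = {}
    pooled = {}
    for name, wedge in wedges.items():
        sel = ann & wedge
        if not np.any(sel):
            sector_intensity[name] = np.nan
            sector_r[name] = np.nan
            pooled[name] = 0.0
            continue
        sector_intensity[name] = float(total[sel].mean())
        p_sum, q_sum = float(ipar[sel].sum()), float(iperp[sel].sum())
        pooled[name] = p_sum + q_sum
        sector_r[name] = (
            anisotropy(p_sum, q_sum, g) if p_sum + q_sum > 0 else np.nan
        )
    tb = pooled["top"] + pooled["bottom"]
    contrast = (pooled["left"] + pooled["right"]) / tb if tb > 0 else np.inf
    return AnisotropyResult(
        r_image=r_image,
        sector_intensity=sector_intensity,
        sector_r=sector_r,
        n_photons=int(total[ann].sum()),
        contrast_ratio=float(contrast),
        center_px=center_px,
        metadata={"inner_radius_px": inner_radius_px, "outer_radius_px": outer_radius_px},
    )


def short_fraction_series(
    datasets: Sequence[FLIMDataset],
    mask: np.ndarray | None = None,
    **fit_kwargs,
) -> list[tuple[float, float, float]]:
    """Pooled two-component fit per dataset: (power, f_short, SE) rows."""
    out = []
    for ds in datasets:
        fit = fit_decay(ds.pooled_histogram(mask), n_components=2, **fit_kwargs)
        out.append((ds.laser_power, fit.f_short, fit.fisher_se_f_short))
    return out


def power_trend(
    series: Sequence[tuple[float, float, float]],
) -> dict:
    """Weighted least-squares trend of f_short vs laser power.

    ``series`` rows are (power, f_short, SE).  Returns the slope, its 95 %
    confidence interval, and the per-power table.  Fewer than 3 distinct
    powers is an error.
    """
    rows = [(float(p), float(f), float(se)) for p, f, se in series]
    powers = np.array([r[0] for r in rows])
    if np.unique(powers).size < 3:
        raise DataError("power trend needs >= 3 distinct laser powers")
    f = np.array([r[1] for r in rows])
    se = np.array([r[2] for r in rows])
    good = np.isfinite(se) & (se > 0)
    if good.sum() >= rows.__len__() // 2 + 1:
        floor = se[good].min()
        w = 1.0 / np.clip(se, floor, None) ** 2
    else:  # no usable SEs: ordinary least squares
        w = np.ones_like(f)
    model = sm.WLS(f, sm.add_constant(powers), weights=w).fit()
    slope = float(model.params[1])
    ci = model.conf_int(alpha=0.05)
    return {
        "slope": slope,
        "slope_ci": (float(ci[1][0]), float(ci[1][1])),
        "intercept": float(model.params[0]),
        "table": rows,
        "pvalue": float(model.pvalues[1]),
    }
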