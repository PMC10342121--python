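"""Mixture-series calibration of the resonance bias.

A validation series of known lutein/zeaxanthin mixtures is analyzed with
the same estimator used on tissue maps (nu1 deconvolution or CLS); the
per-level mean estimated zeaxanthin fraction vs the true fraction is the
validation dependency.  Because the resonance cross-sections of the two
pigments differ, the raw estimated fraction is biased (zeaxanthin
overrepresented at 514 nm); the empirical mean curve is inverted to
correct fractions estimated from tissue data.  The linear fit through the
level means summarizes the dependency (slope, intercept, R^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .basis import PigmentBasis
from .cls import cls_fit
from .errors import DataError, NumericalError
from .nu1 import fit_nu1_gaussians
from .spectra import RamanSpectrum

__all__ = ["CalibrationCurve", "estimate_fraction", "build_calibration", "invert_calibration"]


@dataclass
class CalibrationCurve:
    """Validation dependency: mean estimated fraction per true-fraction level."""

    levels: np.ndarray
    mean_estimated: np.ndarray
    sd_estimated: np.ndarray
    n_reps: int
    estimator: str
    laser_nm: int
    slope: float
    intercept: float
    r_squared: float
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "levels": self.levels.tolist(),
            "mean_estimated": self.mean_estimated.tolist(),
            "sd_estimated": self.sd_estimated.tolist(),
            "n_reps": self.n_reps,
            "estimator": self.estimator,
            "laser_nm": self.laser_nm,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            levels=np.asarray(d["levels"], float),
            mean_estimated=np.asarray(d["mean_estimated"], float),
            sd_estimated=np.asarray(d["sd_estimated"], float),
            n_reps=int(d["n_reps"]),
            estimator=d["estimator"],
            laser_nm=int(d["laser_nm"]),
            slope=float(d["slope"]),
            intercept=float(d["intercept"]),
            r_squared=float(d["r_squared"]),
            metadata=d.get("metadata", {}),
        )


def estimate_fraction(
    spectrum: RamanSpectrum, estimator_config: dict | None = None
) -> float:
    """Raw (uncorrected) estimated zeaxanthin fraction of one spectrum.

    ``estimator_config`` keys: ``estimator`` ("nu1", default, or "cls"),
    ``basis`` (a :class:`PigmentBasis`, required for "cls" references and
    ignored by "nu1"), ``constraints`` (passed to the nu1 fit),
    ``nuisance_terms`` (passed to CLS).
    """
    cfg = dict(estimator_config or {})
    estimator = cfg.get("estimator", "nu1")
    if estimator == "nu1":
        # estimation default pins the component centers: with only ~5 cm^-1
        # separation, free centers make the decomposition noise-unstable
        constraints = dict(cfg.get("constraints") or {})
        constraints.setdefault("fix_centers", True)
        constraints.setdefault("width_starts", (14.0,))
        constraints.setdefault("local_offset", True)
        fit = fit_nu1_gaussians(spectrum, constraints=constraints)
        return fit.raw_fraction_zea
    if estimator == "cls":
        basis: PigmentBasis | None = cfg.get("basis")
        if basis is None:
            raise DataError("CLS estimator needs 'basis' in estimator_config")
        refs = {
            p: basis.reference_spectrum(p, wavenumbers=spectrum.wavenumbers)
            for p in ("lut", "zea")
        }
        res = cls_fit(
            spectrum, refs, nonneg=True, nuisance_terms=cfg.get("nuisance_terms", ("offset",))
        )
        if res.raw_fraction_zea is None:
            raise NumericalError("CLS returned all-zero coefficients")
        return res.raw_fraction_zea
    raise DataError(f"unknown estimator {estimator!r}")


def build_calibration(
    mixture_dataset: Sequence[tuple[RamanSpectrum, object]],
    estimator_config: dict | None = None,
) -> CalibrationCurve:
    """Build the validation dependency from a mixture series.

    ``mixture_dataset`` is a sequence of (spectrum, truth) pairs as
    produced by :func:`xanthomap.synthetic.synth_mixture_series`; the
    truth may be a ``SyntheticTruth`` or a plain float true fraction.
    Produces per-level mean +- SD of the estimated fraction, and an
    ordinary least-squares line through the level means with its R^2
    computed on the means (matching a validation plot of averaged points).
    """
    if len(mixture_dataset) == 0:
        raise DataError("empty mixture dataset")
    cfg = dict(estimator_config or {})
    estimator = cfg.get("estimator", "nu1")

    by_level: dict[float, list[float]] = {}
    failures: dict[float, list[str]] = {}
    laser = None
    for spectrum, truth in mixture_dataset:
        true_f = float(getattr(truth, "f_zea", truth))
        laser = spectrum.laser_nm if laser is None else laser
        if spectrum.laser_nm != laser:
            raise DataError("mixture series mixes laser lines; calibrate per laser")
        try:
            est = estimate_fraction(spectrum, cfg)
        except Exception as exc:  # failures are collected per level
            failures.setdefault(true_f, []).append(str(exc))
            continue
        by_level.setdefault(true_f, []).append(est)

    levels = np.array(sorted(set(by_level) | set(failures)))
    if levels.size < 2:
        raise DataError("calibration needs at least two fraction levels")
    empty = [lv for lv in levels if not by_level.get(lv)]
    if empty:
        raise NumericalError(
            f"no successful fits at levels {empty}",
            diagnostics={lv: failures.get(lv, []) for lv in empty},
        )
    mean = np.array([np.mean(by_level[lv]) for lv in levels])
    sd = np.array([np.std(by_level[lv], ddof=1) if len(by_level[lv]) > 1 else 0.0 for lv in levels])
    n_reps = int(min(len(by_level[lv]) for lv in levels))

    slope, intercept = np.polyfit(levels, mean, 1)
    fitted = slope * levels + intercept
    ss_tot = float(np.sum((mean - mean.mean()) ** 2))
    r_squared = 1.0 - float(np.sum((mean - fitted) ** 2)) / ss_tot if ss_tot > 0 else -np.inf

    return CalibrationCurve(
        levels=levels,
        mean_estimated=mean,
        sd_estimated=sd,
        n_reps=n_reps,
        estimator=estimator,
        laser_nm=int(laser),
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r_squared),
    )


def invert_calibration(raw_fraction, curve: CalibrationCurve):
    """Map raw estimated fraction(s) back to true fraction(s).

    Monotone piecewise-linear interpolation of (mean_estimated -> true),
    with the endpoints pinned so raw = 0 and raw = 1 map to 0 and 1; the
    output is clamped to [0, 1].  A non-monotone mean curve is a
    calibration error (pool more replicates or re-estimate).
    """
    x = np.asarray(curve.mean_estimated, float)
    y = np.asarray(curve.levels, float)
    if np.any(np.diff(x) < 0):
        raise DataError(
            "mean estimated curve is not monotone non-decreasing; "
            "pool more replicates or re-estimate the calibration"
        )
    # pin the endpoints of the inverse map
    if x[0] > 0:
        x, y = np.insert(x, 0, 0.0), np.insert(y, 0, 0.0)
    if x[-1] < 1:
        x, y = np.append(x, 1.0), np.append(y, 1.0)
    raw = np.clip(np.asarray(raw_fraction, float), 0.0, 1.0)
    corrected = np.interp(raw, x, y)
    out = np.clip(corrected, 0.0, 1.0)
    return float(out) if np.isscalar(raw_fraction) else out
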