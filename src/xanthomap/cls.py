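"""Classical least-squares (CLS) unmixing of full spectra.

A measured spectrum is modeled as a non-negative combination of fixed
pure-component reference traces plus optional nuisance terms (constant
offset, linear slope).  The unconstrained solve is the exact
normal-equation solution; the constrained solve enforces non-negativity
on the reference coefficients only (nuisance terms stay free).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear

from .errors import DataError
from .nu1 import fractions_from_areas
from .spectra import RamanSpectrum

__all__ = ["CLSResult", "cls_fit"]


@dataclass
class CLSResult:
    """Coefficients of a CLS fit against named references."""

    coefficients: dict[str, float]
    nuisance: dict[str, float]
    residual_norm: float
    raw_fraction_zea: float | None
    corrected_fraction_zea: float | None


def cls_fit(
    spectrum: RamanSpectrum,
    references: dict[str, np.ndarray],
    nonneg: bool = True,
    nuisance_terms: tuple[str, ...] = ("offset",),
    cross_sections: dict[str, float] | None = None,
) -> CLSResult:
    """Least-squares fit of ``spectrum`` onto the reference traces.

    ``references`` maps component names to traces on the spectrum's own
    wavenumber axis.  ``nuisance_terms`` may contain ``"offset"`` and
    ``"slope"``.  When the references are named ``lut`` and ``zea``,
    fractions are derived from the coefficients with cross-section
    correction exactly as in :func:`xanthomap.nu1.fractions_from_areas`;
    ``cross_sections`` maps names to s(p, L) (defaults to 1).
    """
    if len(references) < 2:
        raise DataError("CLS needs at least two references")
    y = spectrum.intensity
    names = list(references)
    cols = []
    for name in names:
        ref = np.asarray(references[name], dtype=float)
        if ref.shape != y.shape:
            raise DataError(
                f"reference {name!r} has {ref.size} bins, spectrum has {y.size}"
            )
        cols.append(ref)
    nuisance_cols = []
    for term in nuisance_terms:
        if term == "offset":
            nuisance_cols.append(np.ones_like(y))
        elif term == "slope":
            x = spectrum.wavenumbers
            nuisance_cols.append((x - x.mean()) / (x.max() - x.min()))
        else:
            raise DataError(f"unknown nuisance term {term!r}")
    design = np.column_stack(cols + nuisance_cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DataError("reference set is rank-deficient (linearly dependent traces)")

    n_ref = len(names)
    if nonneg:
        lb = np.concatenate([np.zeros(n_ref), np.full(len(nuisance_cols), -np.inf)])
        ub = np.full(design.shape[1], np.inf)
        sol = lsq_linear(design, y, bounds=(lb, ub), method="bvls")
        coef = sol.x
    else:
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    residual_norm = float(np.linalg.norm(y - fitted))

    coefficients = {n: float(c) for n, c in zip(names, coef[:n_ref])}
    nuisance = {t: float(c) for t, c in zip(nuisance_terms, coef[n_ref:])}

    raw = corrected = None
    if set(names) >= {"lut", "zea"}:
        cs = cross_sections or {}
        c_l = max(coefficients["lut"], 0.0)
        c_z = max(coefficients["zea"], 0.0)
        if c_l + c_z > 0:
            raw, corrected = fractions_from_areas(
                c_l, c_z, cs.get("lut", 1.0), cs.get("zea", 1.0)
            )
    return CLSResult(
        coefficients=coefficients,
        nuisance=nuisance,
        residual_norm=residual_norm,
        raw_fraction_zea=raw,
        corrected_fraction_zea=corrected,
    )
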