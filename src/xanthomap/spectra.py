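"""In-memory containers for Raman spectra and spectral maps.

A :class:`RamanSpectrum` is one wavenumber-indexed intensity trace tagged
with the excitation laser line; a :class:`SpectralMap` is a rectangular
grid of spectra sharing one wavenumber axis, either an XY retina image or
an XZ depth scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import DataError

#: Laser lines the analysis knows about (argon 488 / 514 nm).
KNOWN_LASERS = (488, 514)


@dataclass
class RamanSpectrum:
    """One Raman spectrum: intensity vs wavenumber, plus provenance.

    Parameters
    ----------
    wavenumbers : array of float
        Strictly ascending axis in cm^-1.
    intensity : array of float
        Detector counts, same length as ``wavenumbers``.
    laser_nm : int
        Excitation line, 488 or 514.
    metadata : dict
        Free-form provenance (preprocessing flags, generator truth pointers...).
    """

    wavenumbers: np.ndarray
    intensity: np.ndarray
    laser_nm: int
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumbers.shape != self.intensity.shape:
            raise DataError("wavenumber and intensity arrays differ in length")
        if self.wavenumbers.ndim != 1 or self.wavenumbers.size < 2:
            raise DataError("a spectrum needs a 1-D axis with at least two bins")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise DataError("wavenumber axis must be strictly ascending")
        if int(self.laser_nm) not in KNOWN_LASERS:
            raise DataError(f"unknown laser line {self.laser_nm} nm (expected one of {KNOWN_LASERS})")
        self.laser_nm = int(self.laser_nm)

    @property
    def n_bins(self) -> int:
        return self.wavenumbers.size

    def copy(self, intensity: np.ndarray | None = None, **meta: Any) -> "RamanSpectrum":
        """Return a copy, optionally with replaced intensities and extra metadata."""
        new_meta = dict(self.metadata)
        new_meta.update(meta)
        return RamanSpectrum(
            self.wavenumbers.copy(),
            self.intensity.copy() if intensity is None else np.asarray(intensity, float),
            self.laser_nm,
            new_meta,
        )


@dataclass
class SpectralMap:
    """A grid of spectra on a shared wavenumber axis.

    ``intensity`` has shape (n_rows, n_cols, n_bins).  For an XY map rows
    index y (µm, upward) and columns x (µm, rightward); for an XZ map rows
    index z (depth, µm) and columns x.  ``pixel_size_um`` is (row pitch,
    column pitch).
    """

    plane: str  # "XY" or "XZ"
    wavenumbers: np.ndarray
    intensity: np.ndarray  # (n_rows, n_cols, n_bins)
    pixel_size_um: tuple[float, float]
    laser_nm: int
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.plane not in ("XY", "XZ"):
            raise DataError(f"plane must be 'XY' or 'XZ', got {self.plane!r}")
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise DataError("map intensity must be (rows, cols, bins)")
        if self.intensity.shape[-1] != self.wavenumbers.size:
            raise DataError("map spectral dimension does not match the wavenumber axis")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise DataError("wavenumber axis must be strictly ascending")
        pr, pc = self.pixel_size_um
        if pr <= 0 or pc <= 0:
            raise DataError("pixel size must be positive")
        self.laser_nm = int(self.laser_nm)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape[:2]

    def pixel(self, row: int, col: int) -> RamanSpectrum:
        """Extract one pixel as a standalone spectrum."""
        return RamanSpectrum(
            self.wavenumbers,
            self.intensity[row, col],
            self.laser_nm,
            {"row": row, "col": col},
        )

    def pixel_centers_um(self) -> tuple[np.ndarray, np.ndarray]:
        """Continuous coordinates of pixel centers: (row_coords, col_coords) in µm.

        Origin at the lower-left pixel corner; centers at (i + 0.5) * pitch.
        """
        n_rows, n_cols = self.shape
        pr, pc = self.pixel_size_um
        return (np.arange(n_rows) + 0.5) * pr, (np.arange(n_cols) + 0.5) * pc
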