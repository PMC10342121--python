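"""Containers for polarized TCSPC data.

A :class:`DecayHistogram` holds one pair of photon-arrival histograms
(parallel / perpendicular detection channels, default 16 ps bins); a
:class:`FLIMDataset` is an image of such histograms plus acquisition
metadata (G factor, laser power).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import DataError

DEFAULT_BIN_PS = 16.0


@dataclass
class DecayHistogram:
    """Per-pixel (or pooled) polarized decay histograms.

    ``time_ps`` holds the left edge of each bin; both channels are
    non-negative integer counts per bin.
    """

    time_ps: np.ndarray
    counts_parallel: np.ndarray
    counts_perpendicular: np.ndarray
    g_factor: float = 1.0
    laser_power: float = 1.0
    pixel: tuple[int, int] | None = None

    def __post_init__(self):
        self.time_ps = np.asarray(self.time_ps, dtype=float)
        self.counts_parallel = np.asarray(self.counts_parallel)
        self.counts_perpendicular = np.asarray(self.counts_perpendicular)
        if not (
            self.time_ps.shape
            == self.counts_parallel.shape
            == self.counts_perpendicular.shape
        ):
            raise DataError("time axis and channel histograms must share one length")
        if self.time_ps.size < 2:
            raise DataError("a decay histogram needs at least two bins")
        steps = np.diff(self.time_ps)
        if not np.allclose(steps, steps[0]) or steps[0] <= 0:
            raise DataError("time bins must be uniform and positive")
        for name, c in (
            ("parallel", self.counts_parallel),
            ("perpendicular", self.counts_perpendicular),
        ):
            if np.any(c < 0):
                raise DataError(f"negative counts in {name} channel")
            if not np.all(np.equal(np.mod(c, 1), 0)):
                raise DataError(f"non-integral counts in {name} channel")
        if self.g_factor <= 0:
            raise DataError("g_factor must be > 0")

    @property
    def bin_ps(self) -> float:
        return float(self.time_ps[1] - self.time_ps[0])

    @property
    def counts_total(self) -> np.ndarray:
        """Channel-summed histogram (parallel + perpendicular)."""
        return self.counts_parallel + self.counts_perpendicular


@dataclass
class FLIMDataset:
    """Image of polarized decay histograms: arrays of shape (ny, nx, nt)."""

    time_ps: np.ndarray
    parallel: np.ndarray
    perpendicular: np.ndarray
    g_factor: float = 1.0
    laser_power: float = 1.0
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.time_ps = np.asarray(self.time_ps, dtype=float)
        self.parallel = np.asarray(self.parallel)
        self.perpendicular = np.asarray(self.perpendicular)
        if self.parallel.shape != self.perpendicular.shape or self.parallel.ndim != 3:
            raise DataError("channel arrays must both be (ny, nx, nt)")
        if self.parallel.shape[-1] != self.time_ps.size:
            raise DataError("time axis length does not match histograms")
        if self.g_factor <= 0:
            raise DataError("g_factor must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.parallel.shape[:2]

    @property
    def bin_ps(self) -> float:
        return float(self.time_ps[1] - self.time_ps[0])

    def intensity_images(self) -> tuple[np.ndarray, np.ndarray]:
        """Time-integrated per-pixel counts: (parallel, perpendicular)."""
        return (
            self.parallel.sum(axis=-1).astype(float),
            self.perpendicular.sum(axis=-1).astype(float),
        )

    def pixel_histogram(self, row: int, col: int) -> DecayHistogram:
        return DecayHistogram(
            self.time_ps,
            self.parallel[row, col],
            self.perpendicular[row, col],
            g_factor=self.g_factor,
            laser_power=self.laser_power,
            pixel=(row, col),
        )

    def pooled_histogram(self, mask: np.ndarray | None = None) -> DecayHistogram:
        """Sum histograms over a boolean pixel mask (whole image when None)."""
        if mask is None:
            mask = np.ones(self.shape, dtype=bool)
        return DecayHistogram(
            self.time_ps,
            self.parallel[mask].sum(axis=0),
            self.perpendicular[mask].sum(axis=0),
            g_factor=self.g_factor,
            laser_power=self.laser_power,
        )
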