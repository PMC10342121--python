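"""Pure-component spectral model for lutein and the zeaxanthins.

Each pigment's Raman spectrum over 800-1800 cm^-1 is a sum of Gaussian
bands; the dominant nu1 (C=C stretch) band sits at 1526 cm^-1 for lutein
and 1521 cm^-1 for the zeaxanthins (Zea and meso-Zea are treated jointly
as one spectral component).  Resonance enhancement is expressed through a
per-(pigment, laser) relative scattering cross-section s(p, L): 488 nm is
in resonance with lutein's 0-0 absorption transition, while 514 nm lies
beyond lutein's main absorption band but still inside that of the
zeaxanthins, so s(zea, 514) > s(lut, 514).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

PIGMENTS = ("lut", "zea")
LASERS = (488, 514)

#: nu1 band maxima (cm^-1) of lutein and the zeaxanthins.
NU1_CENTER = {"lut": 1526.0, "zea": 1521.0}

#: FWHM-to-sigma conversion for a Gaussian: FWHM = 2*sqrt(2 ln 2)*sigma.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

AXIS_LO, AXIS_HI = 800.0, 1800.0


@dataclass(frozen=True)
class GaussianBand:
    """One Gaussian component band: center (cm^-1), FWHM (cm^-1), relative amplitude."""

    center: float
    fwhm: float
    amplitude: float

    def __post_init__(self):
        if not (AXIS_LO <= self.center <= AXIS_HI):
            raise ConfigurationError(
                f"band center {self.center} cm^-1 outside [{AXIS_LO}, {AXIS_HI}]"
            )
        if self.fwhm <= 0:
            raise ConfigurationError(f"band fwhm must be > 0, got {self.fwhm}")
        if self.amplitude <= 0:
            raise ConfigurationError(f"band amplitude must be > 0, got {self.amplitude}")

    @property
    def sigma(self) -> float:
        return self.fwhm * FWHM_TO_SIGMA

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        nu = np.asarray(wavenumbers, dtype=float)
        return self.amplitude * np.exp(-((nu - self.center) ** 2) / (2.0 * self.sigma**2))


# Default band lists.  nu1 parameters follow the measured band maxima; the
# secondary carotenoid bands nu2 (~1157, C-C stretch) and nu3 (~1008, methyl
# rock) are literature-typical positions included so that full-spectrum CLS
# is well conditioned.  Amplitudes are relative to nu1 = 1.
_DEFAULT_BANDS = {
    "lut": (
        GaussianBand(NU1_CENTER["lut"], 14.0, 1.0),
        GaussianBand(1157.0, 12.0, 0.60),
        GaussianBand(1008.0, 10.0, 0.35),
    ),
    "zea": (
        GaussianBand(NU1_CENTER["zea"], 14.0, 1.0),
        GaussianBand(1157.0, 12.0, 0.55),
        GaussianBand(1008.0, 10.0, 0.30),
    ),
}

# Relative resonance-Raman scattering cross-sections.  488 nm resonates with
# lutein's 0-0 transition; 514 nm sits beyond lutein's main absorption band
# but within the zeaxanthin band, so the zeaxanthin signal is enhanced
# relative to lutein there.  Values are model parameters chosen so that the
# simulated validation curve reproduces the observed bias direction and a
# linear-fit R^2 inside the reported 0.93-0.99 range.
_DEFAULT_CROSS_SECTIONS = {
    ("lut", 488): 1.0,
    ("zea", 488): 0.8,
    ("lut", 514): 0.5,
    ("zea", 514): 1.0,
}


@dataclass
class PigmentBasis:
    """Band lists, cross-sections and the shared wavenumber axis.

    ``bands[pigment]`` is a tuple of :class:`GaussianBand`;
    ``cross_sections[(pigment, laser)]`` is the relative scattering
    efficiency s(p, L) > 0.
    """

    bands: dict[str, tuple[GaussianBand, ...]]
    cross_sections: dict[tuple[str, int], float]
    wavenumbers: np.ndarray = field(
        default_factory=lambda: np.arange(AXIS_LO, AXIS_HI + 0.5, 1.0)
    )

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise ConfigurationError("basis wavenumber axis must be strictly ascending")
        if self.wavenumbers[0] < AXIS_LO or self.wavenumbers[-1] > AXIS_HI:
            raise ConfigurationError(
                f"basis axis must lie within [{AXIS_LO}, {AXIS_HI}] cm^-1"
            )
        for p in PIGMENTS:
            if p not in self.bands or not self.bands[p]:
                raise ConfigurationError(f"missing band list for pigment {p!r}")
        for p in PIGMENTS:
            for laser in LASERS:
                s = self.cross_sections.get((p, laser))
                if s is None or s <= 0:
                    raise ConfigurationError(
                        f"cross_section[({p!r}, {laser})] must be > 0, got {s}"
                    )
        # nu1 must be the largest-amplitude band of every pigment.
        for p, bands in self.bands.items():
            top = max(bands, key=lambda b: b.amplitude)
            if top is not self.nu1_band(p):
                raise ConfigurationError(
                    f"nu1 must be the largest-amplitude band for pigment {p!r}"
                )

    def nu1_band(self, pigment: str) -> GaussianBand:
        """The band with the largest amplitude (by construction the nu1 band)."""
        return max(self.bands[pigment], key=lambda b: b.amplitude)

    def cross_section(self, pigment: str, laser_nm: int) -> float:
        return self.cross_sections[(pigment, int(laser_nm))]

    def component_shape(self, pigment: str, wavenumbers: np.ndarray | None = None) -> np.ndarray:
        """Unit-concentration band shape B_p(nu), without resonance weighting."""
        nu = self.wavenumbers if wavenumbers is None else np.asarray(wavenumbers, float)
        out = np.zeros_like(nu)
        for band in self.bands[pigment]:
            out += band.profile(nu)
        return out

    def reference_spectrum(
        self,
        pigment: str,
        laser_nm: int | None = None,
        include_cross_section: bool = False,
        wavenumbers: np.ndarray | None = None,
    ) -> np.ndarray:
        """Pure-component reference trace.

        With ``include_cross_section`` the trace is what a unit-concentration
        pure sample would measure at that laser, s(p, L) * B_p(nu); without it
        (the default used as the CLS reference) it is the bare shape B_p.
        """
        shape = self.component_shape(pigment, wavenumbers)
        if include_cross_section:
            if laser_nm is None:
                raise ConfigurationError("laser_nm required when including the cross-section")
            shape = self.cross_section(pigment, laser_nm) * shape
        return shape


def make_default_basis(config: dict | None = None) -> PigmentBasis:
    """Build the packaged default basis, optionally overriding parts of it.

    ``config`` may contain keys ``bands`` (pigment -> list of (center, fwhm,
    amplitude) triples), ``cross_sections`` ((pigment, laser) -> s or
    "pigment_laser" string keys) and ``wavenumber_step`` (cm^-1).  Invalid
    band parameters raise :class:`ConfigurationError` naming the field.
    """
    config = dict(config or {})
    bands = {p: _DEFAULT_BANDS[p] for p in PIGMENTS}
    cross = dict(_DEFAULT_CROSS_SECTIONS)
    step = 1.0

    for key in config:
        if key not in ("bands", "cross_sections", "wavenumber_step"):
            raise ConfigurationError(f"unknown basis config key {key!r}")
    if "bands" in config:
        for p, triples in config["bands"].items():
            if p not in PIGMENTS:
                raise ConfigurationError(f"unknown pigment {p!r} in bands config")
            bands[p] = tuple(GaussianBand(*t) for t in triples)
    if "cross_sections" in config:
        for key, value in config["cross_sections"].items():
            if isinstance(key, str):
                pigment, laser = key.rsplit("_", 1)
                key = (pigment, int(laser))
            cross[(key[0], int(key[1]))] = float(value)
    if "wavenumber_step" in config:
        step = float(config["wavenumber_step"])
        if step <= 0:
            raise ConfigurationError(f"wavenumber_step must be > 0, got {step}")

    axis = np.arange(AXIS_LO, AXIS_HI + step / 2, step)
    return PigmentBasis(bands=bands, cross_sections=cross, wavenumbers=axis)
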