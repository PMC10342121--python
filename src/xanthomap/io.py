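"""Readers and writers for the on-disk formats.

Formats: plain-text two-column spectra with ``#`` headers, long-format
text maps (x / y / wavenumber / intensity, the long-format dialect common
to commercial Raman mapping software exports),
an HDF5 container for polarized FLIM data, JSON calibration curves, and
32-bit float TIFF image exports.  Numbers are written with 9 significant
digits, UTF-8, LF line endings; descending wavenumber axes are normalized
to ascending on read.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .calibration import CalibrationCurve
from .errors import DataError
from .flimdata import FLIMDataset
from .spectra import RamanSpectrum, SpectralMap

__all__ = [
    "MapFileDialect",
    "write_spectrum_text",
    "read_spectrum_text",
    "write_map_text",
    "read_map_text",
    "write_flim_h5",
    "read_flim_h5",
    "save_calibration",
    "load_calibration",
    "write_float_tiff",
    "sha256_file",
]

_FMT = "%.9g"


@dataclass(frozen=True)
class MapFileDialect:
    """Long-format map file dialect: column order, delimiter, header marker."""

    columns: tuple[str, str, str, str] = ("x_um", "y_um", "wavenumber_cm1", "intensity")
    delimiter: str = "\t"

    def __post_init__(self):
        if self.delimiter not in ("\t", ","):
            raise DataError("map dialect delimiter must be tab or comma")
        if sorted(self.columns) != sorted(("x_um", "y_um", "wavenumber_cm1", "intensity")):
            raise DataError(f"map dialect columns must be a permutation of the four standard names, got {self.columns}")


# --------------------------------------------------------------------------
# spectra


def write_spectrum_text(spectrum: RamanSpectrum, path) -> Path:
    """Two-column text export with '#'-prefixed headers."""
    path = Path(path)
    lines = [f"# laser_nm: {spectrum.laser_nm}"]
    for key, value in spectrum.metadata.items():
        if isinstance(value, (str, int, float, bool)) or value is None:
            lines.append(f"# {key}: {value}")
    lines.append("# wavenumber_cm1\tintensity")
    for nu, y in zip(spectrum.wavenumbers, spectrum.intensity):
        lines.append(f"{_FMT % nu}\t{_FMT % y}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    return path


def read_spectrum_text(path, laser_nm: int | None = None) -> RamanSpectrum:
    """Parse a two-column spectrum file.

    The laser line is taken from a ``# laser_nm: ...`` header or the
    ``laser_nm`` argument; rows that are not two numbers raise a parse
    error naming the line.
    """
    path = Path(path)
    metadata: dict = {}
    nus, ys = [], []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                metadata[key.strip()] = value.strip()
            continue
        parts = line.replace(",", "\t").split()
        if len(parts) != 2:
            raise DataError(f"{path.name}:{lineno}: expected two columns, got {len(parts)}")
        try:
            nus.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError:
            raise DataError(f"{path.name}:{lineno}: non-numeric value in {parts}") from None
    if laser_nm is None:
        if "laser_nm" not in metadata:
            raise DataError(f"{path.name}: no laser_nm header and none supplied")
        laser_nm = int(float(metadata.pop("laser_nm")))
    else:
        metadata.pop("laser_nm", None)
    nu = np.asarray(nus)
    y = np.asarray(ys)
    if nu.size and nu[0] > nu[-1]:  # descending export: co-sort ascending
        nu, y = nu[::-1].copy(), y[::-1].copy()
    return RamanSpectrum(nu, y, laser_nm, metadata)


# --------------------------------------------------------------------------
# long-format maps


def write_map_text(smap: SpectralMap, path, dialect: MapFileDialect | None = None) -> Path:
    """Long-format text export: one row per (pixel, wavenumber)."""
    dialect = dialect or MapFileDialect()
    path = Path(path)
    rows_um, cols_um = smap.pixel_centers_um()
    n_rows, n_cols = smap.shape
    sep = dialect.delimiter
    out = [
        f"# plane: {smap.plane}",
        f"# laser_nm: {smap.laser_nm}",
        f"# pixel_size_um: {smap.pixel_size_um[0]} {smap.pixel_size_um[1]}",
        "# " + sep.join(dialect.columns),
    ]
    values = {
        "wavenumber_cm1": smap.wavenumbers,
    }
    append = out.append
    for r in range(n_rows):
        for c in range(n_cols):
            values["x_um"] = cols_um[c]
            values["y_um"] = rows_um[r]
            trace = smap.intensity[r, c]
            for b in range(smap.wavenumbers.size):
                values_row = []
                for col in dialect.columns:
                    if col == "wavenumber_cm1":
                        values_row.append(_FMT % smap.wavenumbers[b])
                    elif col == "intensity":
                        values_row.append(_FMT % trace[b])
                    else:
                        values_row.append(_FMT % values[col])
                append(sep.join(values_row))
    path.write_text("\n".join(out) + "\n", encoding="utf-8", newline="\n")
    return path


def read_map_text(
    path,
    dialect: MapFileDialect | None = None,
    laser_nm: int | None = None,
    plane: str | None = None,
) -> SpectralMap:
    """Parse a long-format map file into a :class:`SpectralMap`.

    The grid is inferred from the unique sorted x and y coordinates; the
    pitch must be uniform within 1e-6 relative, and every pixel must carry
    the identical wavenumber set (ragged pixels are a structure error).
    """
    dialect = dialect or MapFileDialect()
    path = Path(path)
    header: dict = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                header[key.strip()] = value.strip()
    df = pd.read_csv(
        path,
        sep=dialect.delimiter,
        comment="#",
        names=list(dialect.columns),
        header=None,
    )
    for col in dialect.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[~pd.to_numeric(df[col], errors="coerce").notna()].index
            raise DataError(
                f"{path.name}: non-numeric values in column {col!r} "
                f"(first bad data row {int(bad[0]) if len(bad) else '?'})"
            )

    xs = np.unique(df["x_um"].to_numpy())
    ys = np.unique(df["y_um"].to_numpy())
    wns = np.unique(df["wavenumber_cm1"].to_numpy())
    n_cols, n_rows, n_bins = xs.size, ys.size, wns.size
    if len(df) != n_rows * n_cols * n_bins:
        sizes = df.groupby(["x_um", "y_um"]).size()
        ragged = sizes[sizes != n_bins]
        raise DataError(
            f"{path.name}: ragged map ({len(df)} rows != {n_rows}x{n_cols}x{n_bins}); "
            f"offending pixels: {list(ragged.index[:5])}"
        )

    def _pitch(coords, axis_name):
        if coords.size < 2:
            return 1.0
        steps = np.diff(coords)
        if np.max(np.abs(steps - steps[0])) > 1e-6 * abs(steps[0]):
            raise DataError(f"{path.name}: non-uniform {axis_name} pitch")
        return float(steps[0])

    pitch_x = _pitch(xs, "x")
    pitch_y = _pitch(ys, "y")

    col_idx = np.searchsorted(xs, df["x_um"].to_numpy())
    row_idx = np.searchsorted(ys, df["y_um"].to_numpy())
    bin_idx = np.searchsorted(wns, df["wavenumber_cm1"].to_numpy())
    cube = np.full((n_rows, n_cols, n_bins), np.nan)
    cube[row_idx, col_idx, bin_idx] = df["intensity"].to_numpy()
    if np.isnan(cube).any():
        raise DataError(f"{path.name}: pixels with unequal wavenumber sets")

    if laser_nm is None:
        if "laser_nm" not in header:
            raise DataError(f"{path.name}: no laser_nm header and none supplied")
        laser_nm = int(float(header["laser_nm"]))
    plane = plane or header.get("plane", "XY")
    return SpectralMap(
        plane=plane,
        wavenumbers=wns,
        intensity=cube,
        pixel_size_um=(pitch_y, pitch_x),
        laser_nm=laser_nm,
        metadata={k: v for k, v in header.items() if k not in ("laser_nm", "plane")},
    )


# --------------------------------------------------------------------------
# FLIM HDF5 container


def write_flim_h5(dataset: FLIMDataset, path) -> Path:
    """HDF5 layout: /parallel, /perpendicular [ny, nx, nt], /time_ps [nt]."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("parallel", data=dataset.parallel.astype(np.uint32))
        h5.create_dataset("perpendicular", data=dataset.perpendicular.astype(np.uint32))
        h5.create_dataset("time_ps", data=dataset.time_ps)
        h5.attrs["g_factor"] = dataset.g_factor
        h5.attrs["laser_power"] = dataset.laser_power
        h5.attrs["bin_ps"] = dataset.bin_ps
        h5.attrs["excitation_nm"] = dataset.metadata.get("excitation_nm", 470)
        h5.attrs["emission_band"] = dataset.metadata.get("emission_band", "550/88")
    return path


def read_flim_h5(path) -> FLIMDataset:
    path = Path(path)
    with h5py.File(path, "r") as h5:
        for name in ("parallel", "perpendicular", "time_ps"):
            if name not in h5:
                raise DataError(f"{path.name}: missing dataset /{name}")
        return FLIMDataset(
            time_ps=h5["time_ps"][...],
            parallel=h5["parallel"][...],
            perpendicular=h5["perpendicular"][...],
            g_factor=float(h5.attrs.get("g_factor", 1.0)),
            laser_power=float(h5.attrs.get("laser_power", 1.0)),
            metadata={
                "excitation_nm": int(h5.attrs.get("excitation_nm", 470)),
                "emission_band": str(h5.attrs.get("emission_band", "550/88")),
            },
        )


# --------------------------------------------------------------------------
# calibration curves, TIFF, checksums


def save_calibration(curve: CalibrationCurve, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(curve.to_dict(), indent=2) + "\n", encoding="utf-8")
    return path


def load_calibration(path) -> CalibrationCurve:
    path = Path(path)
    try:
        return CalibrationCurve.from_dict(json.loads(path.read_text(encoding="utf-8")))
    except (KeyError, ValueError) as exc:
        raise DataError(f"{path.name}: not a calibration curve file ({exc})") from exc


def write_float_tiff(image: np.ndarray, path, pixel_size_um: tuple[float, float] | None = None) -> Path:
    """Single-channel 32-bit float TIFF with pixel-size tags in µm."""
    path = Path(path)
    kwargs = {}
    if pixel_size_um is not None:
        pr, pc = pixel_size_um
        # TIFF resolution is pixels per unit; use centimeters (1 cm = 1e4 µm)
        kwargs["resolution"] = (1e4 / pc, 1e4 / pr)
        kwargs["resolutionunit"] = "CENTIMETER"
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32), **kwargs)
    return path


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
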