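"""Config-driven pipeline: simulate -> preprocess -> calibrate -> unmix -> map -> flim.

The pipeline is configured by a TOML file with sections [run], [basis],
[generator], [preprocess], [nu1], [cls], [calibration], [mapping], [flim];
unknown sections or keys are rejected before any stage runs.  Every run
writes a manifest (config hash, seeds, package version, per-stage log,
sha256 checksum of every output file) so a rerun with the same config is
bit-identical for deterministic stages and statistically identical (same
seeds) otherwise.  A stage failure halts the run with the stage name and
persists partial outputs plus the log.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .basis import make_default_basis
from .calibration import build_calibration
from .errors import ConfigurationError, XanthomapError
from .flim import power_trend, sector_statistics, short_fraction_series
from .io import (
    MapFileDialect,
    read_map_text,
    save_calibration,
    sha256_file,
    write_flim_h5,
    write_float_tiff,
    write_map_text,
    write_spectrum_text,
)
from .mapping import (
    find_center,
    map_pixelwise,
    radial_profile,
    region_ratios,
    segment_regions,
)
from .nu1 import fit_nu1_gaussians
from .preprocess import preprocess_map
from .synthetic import (
    RetinaGeometry,
    synth_axon_flim,
    synth_mixture_series,
    synth_retina_map,
)

__all__ = ["run_pipeline", "validate_config", "DEFAULT_STAGES"]

DEFAULT_STAGES = ("simulate", "preprocess", "calibrate", "unmix", "map")

_ALLOWED_KEYS = {
    "run": {"seed", "outdir", "stages"},
    "basis": {"wavenumber_step", "cross_sections"},
    "generator": {
        "laser_nm",
        "mixture_levels",
        "mixture_reps",
        "mixture_noise_sd",
        "map_noise_sd",
        "geometry",
    },
    "preprocess": {"z_threshold", "window", "crop", "baseline"},
    "nu1": {"center_slack", "width_starts", "fix_centers", "fwhm_bounds"},
    "cls": {"nuisance_terms"},
    "calibration": {"estimator"},
    "mapping": {
        "estimator",
        "corrected",
        "bin_width_um",
        "segmentation",
        "region_diameters_mm",
        "failure_threshold",
    },
    "flim": {
        "orientation",
        "ring_radius_px",
        "ring_width_px",
        "counts_per_pixel",
        "powers",
        "g_factor",
        "tau_short_ps",
        "tau_long_ps",
        "f_short",
        "n_bins",
    },
}
_GEOMETRY_KEYS = {f.lstrip("_") for f in RetinaGeometry.__dataclass_fields__}


def validate_config(config: dict) -> None:
    """Reject unknown sections/keys and inconsistent stage dependencies."""
    for section, content in config.items():
        if section not in _ALLOWED_KEYS:
            raise ConfigurationError(f"unknown config section [{section}]")
        if not isinstance(content, dict):
            raise ConfigurationError(f"section [{section}] must be a table")
        for key in content:
            if key not in _ALLOWED_KEYS[section]:
                raise ConfigurationError(f"unknown key {key!r} in section [{section}]")
    geometry = config.get("generator", {}).get("geometry", {})
    for key in geometry:
        if key not in _GEOMETRY_KEYS:
            raise ConfigurationError(f"unknown key {key!r} in [generator.geometry]")
    stages = config.get("run", {}).get("stages", list(DEFAULT_STAGES))
    for stage in stages:
        if stage not in ("simulate", "preprocess", "calibrate", "unmix", "map", "flim"):
            raise ConfigurationError(f"unknown stage {stage!r}")
    corrected = config.get("mapping", {}).get("corrected", True)
    if "map" in stages and corrected and "calibrate" not in stages:
        raise ConfigurationError(
            "mapping requests calibration-corrected fractions but the "
            "'calibrate' stage is not scheduled"
        )


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(config_path) -> Path:
    """Execute the configured stages; returns the output directory."""
    config_path = Path(config_path)
    with open(config_path, "rb") as fh:
        config = tomllib.load(fh)
    validate_config(config)

    run_cfg = config.get("run", {})
    seed = int(run_cfg.get("seed", 0))
    outdir = Path(run_cfg.get("outdir", "xanthomap_out"))
    if not outdir.is_absolute():
        outdir = config_path.parent / outdir
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(run_cfg.get("stages", DEFAULT_STAGES))

    manifest = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "version": __version__,
        "stages": stages,
        "log": [],
        "files": {},
    }
    state: dict = {"files": []}

    def _log(stage, message):
        manifest["log"].append({"stage": stage, "message": message})

    def _finish():
        for f in state["files"]:
            manifest["files"][str(Path(f).relative_to(outdir))] = sha256_file(f)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )

    basis = make_default_basis(config.get("basis") or None)
    gen_cfg = config.get("generator", {})
    laser = int(gen_cfg.get("laser_nm", 514))
    geometry = RetinaGeometry(
        **{f"{k}": v for k, v in gen_cfg.get("geometry", {}).items()}
    )
    nu1_cfg = config.get("nu1", {})
    constraints = {}
    if "width_starts" in nu1_cfg:
        constraints["width_starts"] = tuple(nu1_cfg["width_starts"])
    if "fix_centers" in nu1_cfg:
        constraints["fix_centers"] = nu1_cfg["fix_centers"]
    if "fwhm_bounds" in nu1_cfg:
        constraints["fwhm_bounds"] = tuple(nu1_cfg["fwhm_bounds"])
    estimator_cfg = {
        "estimator": config.get("mapping", {}).get("estimator", "nu1"),
        "basis": basis,
        "constraints": constraints or None,
    }

    try:
        for stage in stages:
            if stage == "simulate":
                _run_simulate(config, basis, geometry, laser, seed, outdir, state, _log)
            elif stage == "preprocess":
                _run_preprocess(config, outdir, state, _log)
            elif stage == "calibrate":
                _run_calibrate(config, outdir, state, _log)
            elif stage == "unmix":
                _run_unmix(config, constraints, outdir, state, _log)
            elif stage == "map":
                _run_map(config, estimator_cfg, outdir, state, _log)
            elif stage == "flim":
                _run_flim(config, seed, outdir, state, _log)
    except XanthomapError as exc:
        _log("error", f"stage failed: {exc}")
        _finish()
        raise
    _finish()
    return outdir


# --------------------------------------------------------------------------
# stages


def _run_simulate(config, basis, geometry, laser, seed, outdir, state, log):
    gen = config.get("generator", {})
    mixtures_dir = outdir / "mixtures"
    mixtures_dir.mkdir(exist_ok=True)
    series = synth_mixture_series(
        basis,
        laser_nm=laser,
        n_levels=int(gen.get("mixture_levels", 11)),
        n_reps=int(gen.get("mixture_reps", 10)),
        noise_sd=float(gen.get("mixture_noise_sd", 0.02)),
        seed=seed,
    )
    rows = []
    for spec, truth in series:
        name = f"spectrum_L{truth.extras['level']:02d}_R{truth.extras['rep']:02d}.txt"
        state["files"].append(write_spectrum_text(spec, mixtures_dir / name))
        rows.append(
            {
                "file": name,
                "level": truth.extras["level"],
                "rep": truth.extras["rep"],
                "true_f_zea": truth.f_zea,
                "laser_nm": laser,
            }
        )
    truth_csv = mixtures_dir / "truth.csv"
    pd.DataFrame(rows).to_csv(truth_csv, index=False)
    state["files"].append(truth_csv)

    smap, truth = synth_retina_map(
        basis,
        geometry,
        laser_nm=laser,
        seed=seed + 1,
        noise_sd=float(gen.get("map_noise_sd", 0.01)),
    )
    map_path = outdir / "map.txt"
    state["files"].append(write_map_text(smap, map_path))
    xx = truth["radius_mm"]
    truth_df = pd.DataFrame(
        {
            "radius_mm": xx.ravel(),
            "true_f_zea": truth["f_zea"].ravel(),
            "true_total": truth["total"].ravel(),
        }
    )
    truth_path = outdir / "map_truth.csv"
    truth_df.to_csv(truth_path, index=False)
    state["files"].append(truth_path)
    state["series"] = series
    state["map"] = smap
    log("simulate", f"{len(series)} mixture spectra, map {smap.shape}")


def _run_preprocess(config, outdir, state, log):
    if "map" not in state:
        state["map"] = read_map_text(outdir / "map.txt")
    cfg = dict(config.get("preprocess", {}))
    if "crop" in cfg:
        cfg["crop"] = tuple(cfg["crop"])
    state["map"] = preprocess_map(state["map"], cfg)
    path = outdir / "map_preprocessed.txt"
    state["files"].append(write_map_text(state["map"], path))
    log("preprocess", f"preprocessed map {state['map'].shape}")


def _run_calibrate(config, outdir, state, log):
    if "series" not in state:
        raise ConfigurationError("calibrate stage needs the simulate stage output")
    estimator = config.get("calibration", {}).get("estimator", "nu1")
    curve = build_calibration(state["series"], {"estimator": estimator})
    path = outdir / "calibration.json"
    state["files"].append(save_calibration(curve, path))
    state["calibration"] = curve
    log("calibrate", f"R^2 = {curve.r_squared:.4f} over {curve.levels.size} levels")


def _run_unmix(config, constraints, outdir, state, log):
    if "series" not in state:
        raise ConfigurationError("unmix stage needs the simulate stage output")
    rows = []
    for spec, truth in state["series"]:
        fit = fit_nu1_gaussians(spec, constraints=constraints or None)
        row = {k: v for k, v in asdict(fit).items() if k != "residual"}
        row["true_f_zea"] = truth.f_zea
        rows.append(row)
    path = outdir / "unmix.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    state["files"].append(path)
    log("unmix", f"{len(rows)} spectra unmixed")


def _run_map(config, estimator_cfg, outdir, state, log):
    if "map" not in state:
        state["map"] = read_map_text(outdir / "map.txt")
    cfg = config.get("mapping", {})
    calibration = state.get("calibration") if cfg.get("corrected", True) else None
    if cfg.get("corrected", True) and calibration is None:
        raise ConfigurationError("mapping requested corrected fractions without a calibration")
    pmap = map_pixelwise(
        state["map"],
        estimator_cfg,
        calibration,
        failure_threshold=float(cfg.get("failure_threshold", 0.2)),
    )
    center = find_center(pmap)
    profile = radial_profile(pmap, center, float(cfg.get("bin_width_um", 10.0)))
    mode = cfg.get("segmentation", "fixed")
    diameters = tuple(cfg.get("region_diameters_mm", (0.35, 1.0, 2.0)))
    seg = segment_regions(pmap, center, mode=mode, fixed_diameters_mm=diameters, profile=profile)
    regions = region_ratios(pmap, seg)

    for name in ("lut", "zea", "total", "fwhm", "fraction_zea"):
        path = outdir / f"map_{name}.tif"
        write_float_tiff(pmap.images[name], path, pmap.pixel_size_um)
        state["files"].append(path)

    xx, yy = pmap.coordinate_grids_um()
    pix = {"x_um": xx.ravel(), "y_um": yy.ravel(), "failed": pmap.failed.ravel()}
    for name, img in pmap.images.items():
        pix[name] = img.ravel()
    path = outdir / "map_pixels.csv"
    pd.DataFrame(pix).to_csv(path, index=False)
    state["files"].append(path)

    prof_df = pd.DataFrame({"radius_um": profile.radius_um, "n": profile.n})
    for name in profile.mean:
        prof_df[f"mean_{name}"] = profile.mean[name]
        prof_df[f"sd_{name}"] = profile.sd[name]
    path = outdir / "radial_profile.csv"
    prof_df.to_csv(path, index=False)
    state["files"].append(path)

    stats = {
        "center_um": center,
        "boundary_radii_um": seg.boundary_radii_um,
        "segmentation": seg.method,
        "regions": regions,
    }
    path = outdir / "regions.json"
    path.write_text(json.dumps(stats, indent=2, default=float) + "\n", encoding="utf-8")
    state["files"].append(path)
    foveola = regions.get("foveola")
    log("map", f"foveola ratio = {foveola['ratio']:.3f}" if foveola else "no foveola pixels")


def _run_flim(config, seed, outdir, state, log):
    cfg = config.get("flim", {})
    datasets, truth = synth_axon_flim(
        orientation=cfg.get("orientation", "radial"),
        ring_radius_px=float(cfg.get("ring_radius_px", 20.0)),
        ring_width_px=float(cfg.get("ring_width_px", 4.0)),
        counts_per_pixel=float(cfg.get("counts_per_pixel", 400.0)),
        tau_short_ps=float(cfg.get("tau_short_ps", 70.0)),
        tau_long_ps=float(cfg.get("tau_long_ps", 2500.0)),
        f_short=float(cfg.get("f_short", 0.6)),
        power_series=tuple(cfg.get("powers", (0.5, 1.0, 2.0))),
        g_factor=float(cfg.get("g_factor", 1.0)),
        n_bins=int(cfg.get("n_bins", 780)),
        seed=seed + 2,
    )
    for ds in datasets:
        path = outdir / f"axon_power_{ds.laser_power:g}.h5"
        write_flim_h5(ds, path)
        state["files"].append(path)
    series = short_fraction_series(datasets, mask=truth.extras["ring_mask"])
    trend = power_trend(series)
    sectors = sector_statistics(datasets[-1])
    results = {
        "f_short_series": [
            {"power": p, "f_short": f, "se": se} for p, f, se in series
        ],
        "power_slope": trend["slope"],
        "power_slope_ci": trend["slope_ci"],
        "sector_intensity": sectors.sector_intensity,
        "sector_r": sectors.sector_r,
        "contrast_ratio": sectors.contrast_ratio,
    }
    path = outdir / "flim_results.json"
    path.write_text(json.dumps(results, indent=2, default=float) + "\n", encoding="utf-8")
    state["files"].append(path)
    log("flim", f"power slope = {trend['slope']:.3e}")
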