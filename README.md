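# xanthomap

Resonance-Raman and FLIM analysis of the macular xanthophylls — lutein
(Lut) and the zeaxanthins (Zea + *meso*-Zea) — in the human retina.

The two pigments are spectrally almost identical; what separates them is a
5 cm⁻¹ shift of the ν₁ (C=C stretch) Raman band (1526 cm⁻¹ for Lut,
1521 cm⁻¹ for zeaxanthins) and their different resonance conditions under
488 vs 514 nm excitation. `xanthomap` implements the full analysis chain a
spectroscopist needs to turn confocal Raman maps of a retina into pigment
distribution images, and to quantify xanthophyll orientation in axon
membranes from polarized lifetime (TCSPC/FLIM) data:

* **Preprocessing** — cosmic-ray removal (modified z-score of the second
  difference with a curvature-safe scale floor), asymmetric penalized
  least-squares baseline correction, cropping to 800–1800 cm⁻¹.
* **ν₁ deconvolution** — two-Gaussian fit of the ν₁ band
  A_l·G(ν; c_l, σ_l) + A_z·G(ν; c_z, σ_z) by variable projection
  (non-negative amplitudes solved inside the nonlinear search), band FWHM
  measurement, and fractions from component areas:
  f_raw = A_z/(A_z+A_l), f_corr = (A_z/s_z)/(A_z/s_z + A_l/s_l) with
  relative resonance cross-sections s(pigment, laser).
* **CLS unmixing** — non-negative classical least squares of entire
  spectra against pure-component references, with offset/slope nuisance
  terms.
* **Calibration** — validation curves from mixture series (mean estimated
  vs true fraction, OLS line and R² on level means) and bias correction by
  monotone inversion of the empirical mean curve.
* **Mapping** — per-pixel pigment concentration, total, FWHM and fraction
  images; macula center detection; radial profiles; fixed or data-driven
  foveola/fovea/parafovea segmentation; regional Zea:Lut ratios; line
  cross-sections; Z-scan layer profiles.
* **FLIM** — Poisson maximum-likelihood biexponential tail fits,
  short-lifetime amplitude fraction f_short = a_s/(a_s+a_l), anisotropy
  r = (I_∥ − G·I_⊥)/(I_∥ + 2G·I_⊥), photoselection sector statistics of
  axon cross-sections, and the f_short-vs-laser-power trend.
* **Synthetic data** — a first-class generator reproducing the retina's
  pigment geometry (central Zea:Lut ≈ 2, peripheral ≈ 0.3, ~100× total
  concentration contrast between macula and periphery), mixture series,
  Z-scans and polarized axon FLIM images, each with a ground-truth record
  and bit-reproducible seeding.

See `docs/methods.md` for the models, parameter choices and limitations.

## Worked example

```python
import numpy as np
from xanthomap import *
from xanthomap.basis import make_default_basis

basis = make_default_basis()

# 1. pure-component nu1 centers
for name, f, laser in (("lutein", 0.0, 488), ("zeaxanthin", 1.0, 514)):
    spec, _ = synth_spectrum(basis, f, laser_nm=laser)
    fit = fit_nu1_gaussians(spec)
    center = fit.center_lut if f == 0.0 else fit.center_zea
    print(f"{name:10s} nu1 center: {center:7.1f} cm^-1")

# 2. mixture-series calibration at 514 nm (11 levels x 10 replicates)
series = synth_mixture_series(basis, laser_nm=514, n_levels=11, n_reps=10, seed=1)
curve = build_calibration(series)
print(f"validation line: slope {curve.slope:.3f}, R^2 {curve.r_squared:.3f}")

# 3. scaled-down synthetic retina map -> regional pigment ratios
geometry = RetinaGeometry(
    foveola_diameter_mm=0.1, fovea_diameter_mm=0.28, parafovea_diameter_mm=0.5,
    transition_width_mm=0.05, map_extent_mm=0.8, pixel_size_um=40.0,
)
smap, _ = synth_retina_map(basis, geometry, laser_nm=514, seed=7, noise_sd=0.01)
pmap = map_pixelwise(smap, {"basis": basis}, curve)
center = find_center(pmap)
seg = segment_regions(pmap, center, mode="fixed", fixed_diameters_mm=(0.1, 0.28, 0.5))
regions = region_ratios(pmap, seg)
for region in ("foveola", "fovea", "parafovea", "outside"):
    r = regions[region]
    print(f"{region:10s} Zea:Lut = {r['ratio']:.2f}  (n = {r['n']} pixels)")
contrast = regions["foveola"]["mean_total"] / regions["outside"]["mean_total"]
print(f"center-to-periphery concentration contrast: {contrast:.0f}x")
```

Output:

```
lutein     nu1 center:  1526.0 cm^-1
zeaxanthin nu1 center:  1521.0 cm^-1
validation line: slope 0.959, R^2 0.963
foveola    Zea:Lut = 1.97  (n = 4 pixels)
fovea      Zea:Lut = 1.41  (n = 33 pixels)
parafovea  Zea:Lut = 0.69  (n = 84 pixels)
outside    Zea:Lut = 0.30  (n = 279 pixels)
center-to-periphery concentration contrast: 100x
```

The slope < 1 deviation of the validation line reflects the resonance
bias at 514 nm (zeaxanthin overrepresented in the raw Raman fractions);
the calibration inversion removes it, which is why the mapped regional
ratios land on the generator's truth (2.0 in the foveola plateau, 0.3
peripherally, with the intermediate annuli on the descent between them).

## Command line

```bash
xanthomap simulate mixtures --seed 1 --out mix/      # spectra + truth.csv
xanthomap calibrate --in mix/ --out curve.json
xanthomap simulate map --seed 7 --out map.txt
xanthomap preprocess --in map.txt --out map_pp.txt
xanthomap map --in map_pp.txt --calib curve.json --out results/map
xanthomap simulate axon --seed 2 --out flim/
xanthomap flim power-trend --in flim/
xanthomap run --config config.toml                   # full pipeline + manifest
```

Exit codes: 0 ok, 2 configuration error, 3 data error, 4 numerical error.

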