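# Methods

`xanthomap` quantifies the two macular xanthophyll pools of the human
retina — lutein (Lut) and the zeaxanthins (Zea together with its isomer
*meso*-Zea, treated as one spectral component throughout) — from resonance
Raman maps, and analyzes the orientation and lifetime composition of
xanthophylls in axon membranes from polarized FLIM data. Everything is
driven end to end by a synthetic-data generator, so each stage is tested
against known ground truth.

## Spectral model

Each pigment's Raman spectrum over 800–1800 cm⁻¹ is a sum of Gaussian
bands, G(ν) = A·exp(−(ν−c)²/2σ²) with FWHM = 2√(2 ln 2)·σ. The dominant
ν₁ (C=C stretch) band sits at 1526 cm⁻¹ for Lut and 1521 cm⁻¹ for the
zeaxanthins; secondary carotenoid bands at literature-typical positions
(ν₂ ≈ 1157, ν₃ ≈ 1008 cm⁻¹) keep full-spectrum fitting well conditioned.
The default ν₁ FWHM is 14 cm⁻¹ for both pigments, which produces the
visible mixture broadening expected of two equal-width components 5 cm⁻¹
apart.

Resonance enhancement enters as one relative scattering cross-section
s(pigment, laser) per component and laser line. 488 nm is resonant with
Lut's 0-0 absorption transition; 514 nm lies beyond Lut's main absorption
band but inside the zeaxanthin band. Defaults:

| pigment | 488 nm | 514 nm |
|---------|--------|--------|
| lut     | 1.0    | 0.5    |
| zea     | 0.8    | 1.0    |

These are model parameters, not measured values. The 514 nm pair was
chosen so that the simulated raw-fraction validation curve,
f·s_z / (f·s_z + (1−f)·s_l), is biased in the observed direction
(zeaxanthin overrepresented, strongest at 514 nm) with a linear-fit R²
(≈ 0.96) inside the experimentally reported 0.93–0.99 range; a stronger
ratio (s_l = 0.3) would push the curvature outside that range. All four
values are configurable.

A mixture spectrum at total concentration c and zeaxanthin fraction f is

    I(ν) = c · [ f·s_z·B_z(ν) + (1−f)·s_l·B_l(ν) ] + baseline(ν) + ε(ν),

with additive Gaussian noise ε (a Poisson-count option exists), plus
single-bin cosmic-ray spikes of 20–80× the band peak at a configurable
Poisson rate.

## Retina geometry of the generator

The macular truth model is radial around the fovea center, with the
anatomical region disks foveola / fovea / parafovea = 0.35 / 1 / 2 mm
diameter:

* **Zea:Lut ratio** — plateau 2.0 inside the foveola radius, a single
  smooth log-space raised-cosine descent spanning the foveola→parafovea
  radii, and a peripheral plateau 0.3 beyond the parafovea radius. One
  long span (rather than one step per boundary) keeps the foveola plateau
  intact and guarantees every pixel outside the parafovea sits on the
  peripheral plateau.
* **Total concentration** — ~100× higher in the macula than peripherally,
  realized as relative plateau levels 1.0 / 0.95 / 0.10 / 0.01
  (foveola / fovea / parafovea / outside) joined by raised-cosine steps of
  width 0.15 mm in log space. The steps *start* at the foveola and fovea
  boundary radii and *end* at the parafovea radius, so (a) the curvature
  minima of the log profile mark the boundary radii and (b) the peripheral
  floor is fully reached at the parafovea boundary. The mild 5 % foveola
  shoulder keeps the mean concentration inside the fovea disk at ≈ 96 % of
  the central level while still being detectable in the noiseless profile.

Default maps are 3 × 3 mm at 5 µm pixels; the tested configuration is a
scaled-down 1.5 × 1.5 mm map at 10 µm pixels (150 × 150 = 22 500 spectra),
whose corners still contain peripheral (outside-parafovea) pixels. Z-scans
place both pigments in the same Gaussian layer along Z at 1 µm voxel
pitch — the two pigments are co-localized by construction, only their
proportion varies.

Default map noise is 0.01 (absolute, peripheral band peak ≈ 0.46), and the
default mixture-series noise is 0.02 at unit concentration — roughly the
regime where the validation curve's level means reproduce the reported R²
range with 10 replicates.

## Preprocessing

* **Cosmic-ray removal** — Whitaker–Hayes-style modified z-score of the
  second difference, with two adjustments found necessary in testing.
  (1) The MAD scale is floored at 1/20 of the median-filtered signal
  range: a cosmic ray is tens of times the band peak while band curvature
  contributes at most ~1/20 of it per bin, so the floor makes detection
  scale-free — a plain global MAD starts flagging genuine band curvature
  whenever the SNR is high, because the MAD tracks noise while curvature
  tracks signal. (2) Detection and replacement iterate greedily
  (restricted to first-pass candidates), so adjacent twin spikes that
  shadow each other's |z| extremum are both caught. Flagged bins are
  replaced by the local median of clean neighbors inside a 5-bin window;
  all other bins pass through bit-exactly, and the operation is
  idempotent.
* **Baseline correction** — asymmetric penalized least squares (AsLS),
  default smoothness λ = 1e7 and asymmetry p = 1e-3, solved with a banded
  Cholesky factorization (≈ 2 ms per 1001-bin spectrum, which is what
  makes pixel-wise map preprocessing affordable). With these defaults a
  linear ramp under a band is removed to ≈ 0.1 % band-area error. An
  asymmetric estimator never returns an exactly zero baseline under a
  band: on baseline-free input the residual distortion is a few 1e-4 of
  the peak, and on noise-only regions the estimated baseline sits ~2–3
  noise SD below zero — a flat offset the ν₁ fit absorbs (below). An
  iteratively clipped polynomial (degree ≤ 5) is available as an
  alternative.
* **Cropping** — to 800–1800 cm⁻¹ by default.

## ν₁ deconvolution

The ν₁ band is located as the intensity maximum within 1480–1580 cm⁻¹
(window ±40 cm⁻¹); the observed FWHM is measured by linear interpolation
of the half-maximum crossings (zero baseline assumed inside the window).

The two-Gaussian fit uses variable projection: the nonlinear search runs
over centers and widths only, with the two amplitudes solved by
non-negative least squares inside the residual. A deterministic grid of
width starts (10/14/20 cm⁻¹ for each component) makes the fit reproducible
without any random state; ties are broken toward the smaller zeaxanthin
amplitude. Default center bounds are 1526 ± 3 and 1521 ± 3 cm⁻¹.

Two constraint regimes are used deliberately:

* **Characterization** (free, bounded centers) — for recovering the
  component centers themselves from pure or noiseless spectra.
* **Estimation** (pinned centers, free widths, flat local-offset term) —
  whenever a *fraction* is the estimand. With only 5 cm⁻¹ separation at
  14 cm⁻¹ width, free centers make the decomposition practically
  unidentifiable under noise (fraction SD ≈ 0.34 regardless of noise
  level, versus ≈ 0.01–0.03 with pinned centers). The flat offset term
  (sign-split NNLS columns) absorbs the small residual baseline left by
  AsLS on noisy data, which would otherwise inflate low-signal band areas
  by ~10 %.

Pigment fractions derive from component **areas** (A·σ·√2π), the
concentration-proportional quantity: raw = A_z/(A_z+A_l), and
cross-section corrected = (A_z/s_z) / (A_z/s_z + A_l/s_l).

## Classical least squares

Full spectra are regressed onto the packaged unit-concentration component
shapes B_p(ν) (or user-supplied references) with non-negativity on the
reference coefficients (BVLS); an optional constant offset and linear
slope enter as free nuisance columns. The unconstrained solve is the exact
normal-equation solution. Coefficients are treated exactly like ν₁ areas
for fraction computation. On noiseless mixtures, CLS and ν₁-deconvolution
corrected fractions agree to < 1e-3.

## Calibration

A simulated mixture series (default 11 equally spaced true fractions ×
10 replicates) is analyzed with the same estimator used on maps; the
validation dependency is the per-level mean ± SD of the estimated
fraction vs truth, summarized by an OLS line whose R² is computed on the
level means (matching a plot of averaged points). Bias correction inverts
the **empirical mean curve** (monotone piecewise-linear, endpoints pinned
to 0 and 1) rather than the fitted line, preserving the curvature of the
dependency. Curves are tagged with estimator and laser; applying a curve
to a map recorded at a different laser is an error. The calibration is
matrix-blind: it is built from simulated solution-like spectra and applied
to simulated tissue-like maps, which share the same spectral model here
but would not in a real instrument.

## Mapping

Coordinates are continuous µm, origin at the lower-left pixel corner,
x rightward, y upward, pixel centers at (i+0.5)·pitch; Z increases into
the sample. Per pixel, the estimation-regime ν₁ fit yields areas and the
raw fraction; the calibration inversion yields the corrected fraction;
total concentration is the cross-section-corrected A_l/s_l + A_z/s_z
(the raw resonance-weighted band area is kept separately as `nu1_area` —
using it as "total" would overstate the center-to-periphery contrast by
the ratio of the mixture-averaged cross-sections, ≈ 1.35 at 514 nm).
Concentration images are lut = total·(1−f), zea = total·f, so
lut + zea = total exactly. Failed pixels are masked, never interpolated,
and excluded from every downstream statistic; > 20 % failures abort the
map.

The map center is the intensity-weighted centroid of pixels above the
95th percentile of total concentration. Radial profiles are
pixel-count-weighted annulus means (default 10 µm bins). Regional Zea:Lut
ratios are ratios of regional means, not means of pixel ratios, to avoid
noise-amplified division.

Segmentation is either **fixed** (radius thresholds at the anatomical
diameters) or **data-driven**: the log radial total-concentration profile
is smoothed with a 3-tap discrete Gaussian kernel ([0.25, 0.5, 0.25]) and
the three largest-magnitude local minima of its second difference, with
parabolic sub-bin refinement, become the boundary radii sorted by radius.
The kernel is deliberately short: each extra bin of smoothing drags the
curvature minimum of a raised-cosine shoulder inward by roughly one bin,
and with 10 µm bins a wide kernel alone would exceed the foveola-diameter
tolerance. Because the outermost truth transition *ends* at the parafovea
radius, the third detected minimum sits one transition-width inside the
true boundary; the innermost (foveola) boundary is the accurate one, and
the one the data-driven mode is graded on (recovered 0.384 mm vs 0.35 mm
truth at 10 µm pixels, the residual being the smoothing/discretization
bias of curvature-based edge detection).

## FLIM

The axon generator places pixels on an annulus; the xanthophyll transition
dipole at each pixel is fixed in the image plane along the membrane normal
(radial orientation; tangential is its 90° rotation). With horizontal
excitation polarization, per-photon excitation probability ∝ cos²θ and the
parallel/perpendicular detection channels collect cos²θ / sin²θ of the
emission — the fixed in-plane dipole model, with no 3-D wobble, so pixel
anisotropy reaches r = 1 at θ = 0 instead of the 0.4 limit of isotropic
3-D photoselection; this is a deliberate simplification. The measured
perpendicular channel is divided by the instrumental G factor, which the
analysis takes as a known input.

Arrival times follow a biexponential with default τ_short = 70 ps,
τ_long = 2500 ps and **amplitude** fraction f_short = 0.6 (invented
defaults; no lifetimes are printed in the source material). The generator
converts the amplitude fraction to the photon fraction
φ = f·τ_s/(f·τ_s+(1−f)·τ_l) before drawing each photon's component, so the
fitted pre-exponential fraction equals the configured f_short. Histograms
are binned at 16 ps (default 780 bins ≈ 12.5 ns); per-pixel counts are
Poisson and bin positions multinomial, so histogram sums equal the drawn
photon numbers exactly.

Decays are tail-fitted (window starts two bins after the histogram peak,
no IRF deconvolution) by Poisson maximum likelihood on bin-integrated
expectations, Σ aᵢτᵢ(e^(−t₀/τᵢ)−e^(−t₁/τᵢ)) + background. Initialization
is deterministic: a log-linear tail slope anchors τ_long, then a coarse
grid over lifetime pairs with NNLS amplitudes seeds L-BFGS-B (the grid
stage is what keeps the fit out of the background-only local minimum on
low-count histograms). Fitted amplitudes are back-extrapolated to the
decay origin (×e^(t_offset/τ)) before forming
f_short = a_s/(a_s+a_l) — without this the short component, already
decayed by e^(−32/70) at the window start, is underweighted by ~0.1.
Components are relabeled so τ_short < τ_long; lifetimes within 10 % set a
degeneracy flag. The SE of f_short comes from the observed Fisher
information (finite-difference Hessian) with a delta-method gradient that
includes the back-extrapolation terms.

Anisotropy is r = (I_∥ − G·I_⊥)/(I_∥ + 2G·I_⊥) on time-integrated
per-pixel counts (time-resolved r(t) is out of scope). Sector statistics
pool channel counts over 90° wedges centered on the axes before applying
the formula; the orientation contrast is pooled (left+right)/(top+bottom)
intensity. The power trend is a weighted least-squares line of f_short vs
laser power (weights 1/SE²) with a 95 % t confidence interval; laser
powers are free parameters of the simulation.

## What the generator does and does not emulate

It emulates: two-component resonance-weighted band spectra with Gaussian
noise, spikes and baselines; the radial plateau structure of the macular
pigments; co-localized Z-layers; photoselection and biexponential decays
with Poisson statistics. It does **not** emulate instrument optics
(pinhole PSF, spectrograph dispersion), IRF convolution, Poisson detector
noise on Raman maps (Gaussian by default), *meso*-Zea as a third spectral
component, matrix differences between solution calibrants and tissue, or
donor-to-donor variability. Passing tests therefore demonstrate the
correctness and internal consistency of the algorithms under the stated
statistical model, not instrument-level accuracy on real retinas.

## Problem sizes and numerical choices

The tested map is 1.5 × 1.5 mm at 10 µm pixels (22 500 spectra, 1001 bins;
preprocessing ≈ 25 s, fitting ≈ 35 s on one CPU) — the package's chosen
desk-scale configuration of the 3 × 3 mm / 5 µm acquisition geometry.
Mixture calibration uses 110 spectra. FLIM recovery tests pool ~500
annulus pixels (10⁵–10⁶ photons). Optimizer tolerances: ν₁ least squares
xtol = ftol = 1e-12; AsLS weight-convergence 1e-6 (≤ 50 iterations, banded
solve); decay fit L-BFGS-B defaults with deterministic grid init. Map-level
ν₁ fits default to a single width start (14 cm⁻¹) — the full start grid
triples runtime and changes no tested result. Degenerate inputs (flat
spectra, empty regions, zero-length sections, constant images) raise typed
errors rather than returning placeholder values.

## Known limitations

* The ν₁ estimation regime assumes the component centers are exactly the
  configured values; a real instrument would need wavenumber calibration
  first (out of scope).
* The calibration inversion is only as good as the monotonicity of the
  empirical mean curve; heavy noise with few replicates can make it
  non-monotone, which is reported as an error instead of being silently
  smoothed.
* Data-driven segmentation needs marked concentration steps; it reports an
  error on flat or featureless profiles and its outer boundary estimate is
  biased inward by one transition width (see above).
* The FWHM image is exported in cm⁻¹ as-is; no attempt is made to rescale
  it into relative concentration units.
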