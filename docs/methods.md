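# Methods

This note records the model behind each processing stage, the tunable
parameters and their defaults, what the synthetic generator does and does
not emulate, and the numerical choices made where the design was open.

## Frame model

A crossed-VIPA spectrometer frame is modelled as a square interference
pattern on the detector:

* four **Rayleigh spots** at the corners — 2-D Gaussians whose pre-clip
  amplitude far exceeds the camera full well, so they render as clipped
  plateaus at the saturation level;
* **saturation streaks** along the four edges of the square —
  flat-topped ridges at the clip level, emulating the bright
  horizontal/vertical lines that saturated elastic light produces on a
  real sensor;
* the **Brillouin doublet** on the top-left to bottom-right diagonal — a
  1-D Lorentzian along the dispersion axis times a narrow Gaussian
  cross-section perpendicular to it, with Stokes and anti-Stokes peaks
  placed by inverting the calibration relation
  `nu = FSR * min(s, L - s) / L` (s = arc length along the diagonal,
  L = corner-to-corner distance), so calibrating the generator's own
  peak positions returns the configured shift to machine precision;
* a constant **background** plus additive Gaussian **read noise**, and a
  global clip to `[0, saturation]`.

Laser drift and pattern distortion are a single affine map applied to
the whole pattern. The frame is rendered by evaluating the analytic
pattern at the affine pre-image of every pixel, so distorted frames
carry no interpolation error and the true corner/peak positions are
known exactly. Noise is added last, in the detector frame, because it
models camera read noise rather than a property of the optical pattern.

What the generator does **not** emulate: curvature of the diffraction
orders (orders are straight lines, as the straight-edge fits assume),
Poisson photon statistics and fixed-pattern noise, cosmic-ray artefacts,
inter-order content other than one Stokes/anti-Stokes pair, and
wavelength-dependent dispersion nonlinearity. Passing round-trip tests
therefore demonstrates correctness of the *protocol* under its own
assumptions; on real frames the dominant unmodelled effects are order
curvature and the instrument line width (below).

Default generator conditions: 512 x 512 px frame, 400 px square,
FSR 30 GHz, background 100 counts, saturation 60 000 counts, Brillouin
amplitude 3 000 counts, peak signal-to-noise ratio (Brillouin amplitude /
noise sigma) 50. Detector counts and amplitude ratios for real exposures
are not published for this class of instrument, so these are assumptions
chosen to reproduce the qualitative appearance of raw frames: saturated
fiducials, a weak doublet roughly 20x above background, and visible
noise. Material presets carry literature values: methanol 5.6 GHz shift
/ 0.7 GHz linewidth, water 7.5 GHz / 0.65 GHz, and a gelatin-gel preset
defaulting to 8.0 GHz (configurable across the physically sensible
7-9 GHz range) / 0.8 GHz.

## Display enhancement

`contrast_normalize` maps intensities within `alpha` standard deviations
of the frame mean linearly onto [0, 1] and clamps outside; `alpha`
defaults to 0.5 and mu/sigma are whole-frame statistics. The result
feeds only pseudo-colour rendering; the quantitative chain never reads
it, and a test asserts the pipeline output is bit-identical with and
without rendering. A constant frame is rejected rather than displayed:
it indicates an acquisition failure.

## Corner localization

The mask is produced by a Gaussian denoise (sigma 1 px default; the
width is not critical, it only needs to suppress single-pixel noise
before thresholding) and a threshold at 0.95 of the frame maximum, which
isolates the saturated structure. Edge-centre pixels are computed per
mask column for near-horizontal edges and per row for near-vertical
edges; runs longer than 25 px are crossings of the perpendicular streak
and are skipped. Centre pixels are assigned to corners by quadrant
relative to the mask centre of gravity. Per corner, the horizontal and
vertical edge lines are fitted by least squares with one guard: residual
outliers beyond 3 robust standard deviations (MAD) are discarded and the
line refitted, because noise occasionally fragments the perpendicular
streak's mask into short runs that otherwise enter the fit as
high-leverage points several hundred pixels off the edge.

The line intersection is refined by an intensity-weighted centre of
gravity over an 11 x 11 px window (`refine_halfwidth` 5). Two numerical
choices matter here:

* the window is centred **sub-pixel** (bilinear-sampled) rather than at
  the nearest integer pixel: the streaks passing through the window
  contribute mass that follows the window, so an integer-centred window
  biases the centroid toward the pixel grid by several tenths of a
  pixel;
* the centroid is **iterated** (window recentred on the previous
  estimate, up to 10 times, 1e-3 px tolerance): with streak and
  background mass following the window, the recentred iteration's fixed
  point is the symmetric spot centre.

With these choices the median corner error on drifted noisy fixtures
(SNR 20) is ~0.04 px. Saturated pixels enter the centroid as-is; the
centroid of a symmetrically clipped spot is unbiased. A side-length
ratio outside [0.8, 1.25] warns (the straight-line edge model degrades
for strongly non-square patterns) but does not fail.

## Registration

The 4-point correspondence to a canonical axis-aligned square is solved
as an exact projective transform (scikit-image); an affine-restricted
least-squares mode is available (`affine_only`) for cameras where the
distortion is known to be affine. The canonical square (side 400 px
default) is placed at integer pixel margins: a frame already on the
canonical grid then warps without sub-pixel resampling, which keeps the
noiseless round trip exact and avoids gratuitous interpolation
broadening. Warping uses inverse mapping with bilinear interpolation and
zero fill; an exact identity transform returns the input unchanged.

## Spectral extraction and calibration

The band of half-width 10 px around the canonical diagonal is resampled
onto a rectangular grid (one column per ~1 px of arc length), which is
the crop-and-45-degree-rotation of the raw protocol expressed as a
single resampling. Bilinear sampling is used deliberately: cubic splines
reconstruct the smooth line shapes marginally better but ring at the
edges of the clipped Rayleigh regions, and the overshoot lobes can be
segmented as spurious peaks. The spectrum is the per-column maximum; the
Rayleigh positions on the channel axis are `r0 = 0`,
`r1 = n_channels - 1` by construction, inherited from the registered
corners rather than re-estimated from the 1-D trace, which keeps the
calibration consistent with the registration. The channel-to-GHz map is
the piecewise-linear fold `nu(i) = FSR * min(i - r0, r1 - i)/(r1 - r0)`;
a linear dispersion is assumed throughout (a known approximation of this
spectrometer class; nonlinear calibration is out of scope).

Peak segmentation marks a channel as signal when it exceeds the mean of
the surrounding window (half-width 10 channels per side, centre
excluded; an optional multiplier, default 1, is available for noisy
data) and takes maximal runs of signal channels. Channels within 5 of
the Rayleigh positions are masked first. When the pipeline picks one
candidate per side it additionally rejects segments that reach within
one averaging window of the masked zone (there the local mean is still
dominated by the Rayleigh skirt, and boundary effects of the running
mean can detach a skirt run from the mask edge) and segments whose apex
is at >= 80% of the spectrum maximum (the saturated elastic level is not
a fittable line shape); among the survivors the largest apex per side
wins.

## Line-shape fitting

Lorentzian and Gaussian models are FWHM-parameterized with an additive
offset, so the fitted width *is* the linewidth in GHz. Fits are
Levenberg-Marquardt (lmfit) from moment-based starting values (apex
frequency, apex-minus-baseline amplitude, half-maximum-crossing width,
segment-edge offset) with bounds A > 0, G in (0, FSR/2), nu0 inside the
fitted window; iteration budget 200 function evaluations, relative
tolerance 1e-8. The fitted window is the segment padded by `fit_pad`
channels per side (default 15, about one FWHM for the presets): the
offset is only well constrained by wing coverage, and the
Lorentzian-vs-Gaussian distinction also lives in the wings, so the pad
is sized to include at least one FWHM of wing on each side. Reported
quality metrics are the RMS residual and R^2 = 1 - SS_res/SS_tot over
the fitted window.

Stokes and anti-Stokes results are combined as their mean (modes
`stokes` / `anti_stokes` select one side), with the inter-side
asymmetries |delta shift| and |delta FWHM| kept as QC metrics; an
unconverged or missing side flags the record and falls back to the
usable side.

Fitted widths are *apparent* widths: the ~0.6 GHz instrument function of
this spectrometer class is not deconvolved, matching how such linewidths
are usually reported. It is also why a Gaussian fits the data nearly as
well as a Lorentzian — the instrumental convolution pushes the observed
shape toward a Voigt profile.

## Pipeline and maps

`process_frame` executes denoise -> binarize -> locate_corners ->
compute_transform -> warp -> extract_band -> project_max -> calibrate ->
segment_peaks -> fit (both sides) -> combine, wrapping any stage failure
with the stage name. `process_scan` consumes frames one at a time
(memory bounded by one frame plus result records), logs per-frame corner
drift relative to the first frame as the drift-correction audit trail,
and records failed frames as missing map positions rather than aborting
a long scan. Maps are tables of `x_um, y_um, shift_ghz, fwhm_ghz,
r_squared, rms, qc_flags` with rasters per quantity.

`estimate_modulus` implements the standard backscattering relation
v = lambda nu / (2n), M = rho v^2. It is a literature relation supplied
for convenience; refractive index and density must be supplied by the
caller — no material defaults are assumed.

## Problem sizes used in validation

The validation suite generates frames at the default 512 x 512 geometry.
Round-trip checks use 20 seeded frames per material at peak SNR 50 with
random affine drift (translation up to 5 px, shear up to 2%);
registration accuracy uses 100 seeded drifted fixtures at peak SNR 20;
model discrimination uses 100 fitted segments at peak SNR 20; fit
quality uses a single methanol frame at peak SNR 100. These sizes give
stable statistics (standard error of the mean shift a few 0.001 GHz)
while keeping the whole suite fast.

## Known limitations

* Straight-line edge model: strongly curved diffraction orders violate
  the corner line fits and the linear dispersion assumption alike.
* Single inter-order segment: only the square bounded by two adjacent
  Rayleigh peaks is analysed; no multi-order stitching.
* Apparent linewidths (no instrument-function deconvolution, no Voigt).
* Shifts approaching FSR/2 bring the Stokes and anti-Stokes peaks
  together at the spectrum midpoint; the fixed fit pad may then overlap
  the two, and results should be treated with caution.
* The Gaussian-noise generator does not probe robustness to Poisson
  statistics, hot pixels or cosmic rays.
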