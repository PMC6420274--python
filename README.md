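# vipabrill

Automated analysis of imaging data from a crossed-VIPA Brillouin
microscope: registration of the spectrometer pattern, spectral
extraction, frequency calibration and line-shape fitting, packaged as a
Python library with a `vipa-brill` command line tool.

## The problem

Brillouin light scattering (BLS) microscopy maps the viscoelasticity of
biological samples by measuring the GHz-scale frequency shift and
linewidth of light scattered by thermally excited acoustic waves. A
two-stage virtually imaged phase array (VIPA) spectrometer disperses each
spectrum into a 2-D camera frame: the elastic (Rayleigh) light saturates
the detector at the four corners of a square pattern, and the inelastic
Stokes/anti-Stokes Brillouin doublet lies on the diagonal between two
adjacent diffraction orders. Turning a stage scan of thousands of such
frames into stiffness maps requires, per frame and fully unattended:

1. **Rayleigh fiducial localization** — Gaussian denoise, threshold at
   0.95 of the frame maximum, extract the centre pixels of the saturated
   lines forming the square's edges, assign them to corners via the mask
   centre of gravity, intersect per-corner line fits, and refine each
   corner with an intensity-weighted centre of gravity (sub-pixel).
2. **Drift correction** — solve the 4-point homography H mapping the
   detected corners onto a canonical square and resample the frame,
   cancelling laser drift and pattern distortion.
3. **Spectral extraction** — resample the band around the corner-to-corner
   diagonal so the dispersion axis is horizontal, and take the maximum of
   each column as one spectral channel.
4. **Frequency calibration** — with Rayleigh positions R0, R1 one free
   spectral range (FSR, 30 GHz) apart,

       nu_B(i) = FSR * min(i - R0, R1 - i) / (R1 - R0)

   which folds Stokes and anti-Stokes onto one positive-shift axis.
5. **Peak analysis** — segment candidates by a local-average threshold
   and fit FWHM-parameterized Lorentzian (or Gaussian) line shapes

       L(nu) = A (G/2)^2 / ((nu - nu0)^2 + (G/2)^2) + c

   by nonlinear least squares, reporting the shift nu0, linewidth G, the
   RMS residual and R^2, and the Stokes/anti-Stokes combination.

A synthetic frame generator (`vipabrill.fixtures`) renders the whole
pattern analytically — clipped Rayleigh spots and saturation streaks,
Lorentzian doublet placed by inverting the calibration relation, affine
drift, Gaussian read noise — so every stage is validated against exact
ground truth without instrument data. Presets carry the standard-liquid
literature values used for calibration validation (methanol 5.6 GHz /
0.7 GHz, water 7.5 GHz / 0.65 GHz).

## Worked example

```python
import numpy as np
from vipabrill import fixtures, process_frame

rng = np.random.default_rng(7)
truth = fixtures.preset("water", snr=50, seed=7,
                        distortion=fixtures.random_drift(rng))
frame = fixtures.generate_frame(truth)          # 512x512 counts array

result = process_frame(frame)
c = result.combined
print(f"refinement residual: {result.corners.refinement_residual:.3f} px")
print(f"Stokes:      shift {result.stokes_fit.shift:.3f} GHz, "
      f"FWHM {result.stokes_fit.fwhm:.3f} GHz, R^2 {result.stokes_fit.r_squared:.4f}")
print(f"combined:    shift {c.shift:.3f} GHz, FWHM {c.fwhm:.3f} GHz "
      f"(asymmetry {c.shift_asymmetry:.3f} GHz)")
```

prints

```
refinement residual: 0.078 px
Stokes:      shift 7.503 GHz, FWHM 0.655 GHz, R^2 0.9989
combined:    shift 7.501 GHz, FWHM 0.656 GHz (asymmetry 0.004 GHz)
```

The frame was generated with a 7.5 GHz shift, 0.65 GHz linewidth and a
random affine drift of several pixels; the pipeline recovers both to a
few 0.001 GHz after locating the corners to better than 0.1 px
(`refinement_residual` is the mean distance between the line-intersection
estimates and their weighted-centroid refinements — a per-frame QC
number). The small Stokes/anti-Stokes asymmetry is a second QC metric.

The same chain is available from the shell:

```sh
vipa-brill --seed 7 simulate --preset water --snr 50 --drift --out frame.tiff
vipa-brill register frame.tiff --out corners.json
vipa-brill extract frame.tiff --corners corners.json --out spectrum.csv
vipa-brill fit spectrum.csv --model lorentzian --out fit.json
```

and `vipa-brill map manifest.csv --out map.csv` processes a whole stage
scan (manifest columns `path,x_um,y_um`) into a per-position table of
shift, linewidth and fit quality, with failed frames recorded as missing
positions. `vipabrill.estimate_modulus(shift, n, rho, wavelength)`
converts a backscattering shift to a longitudinal modulus
M = rho (lambda nu / 2n)^2; for water-like constants (n = 1.33,
rho = 998 kg/m^3, 532 nm) a 7.5 GHz shift gives 2.25 GPa.

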