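"""Lorentzian / Gaussian line-shape fitting of Brillouin peaks.

Both models are FWHM-parameterized with an additive offset, so the fitted
width is directly the linewidth in GHz:

    lorentzian: A * (G/2)^2 / ((nu - nu0)^2 + (G/2)^2) + c
    gaussian:   A * exp(-4 ln2 (nu - nu0)^2 / G^2) + c

Fits are nonlinear least squares from moment-based starting values, with
bounds keeping the amplitude positive, the width inside (0, FSR/2) and the
centre inside the fitted window.  Fit quality is reported as the RMS
residual and the coefficient of determination R^2 = 1 - SS_res/SS_tot.
Widths are apparent: no deconvolution of the ~0.6 GHz instrument function
is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

from .spectra import CalibratedSpectrum, PeakSegment

_LN2 = np.log(2.0)


class FitError(ValueError):
    pass


def lorentzian(nu, amplitude, center, fwhm, offset):
    """Lorentzian with peak value amplitude+offset at ``center`` and
    half-maximum-above-offset at center +/- fwhm/2."""
    half = fwhm / 2.0
    return amplitude * half**2 / ((nu - center) ** 2 + half**2) + offset


def gaussian(nu, amplitude, center, fwhm, offset):
    """Gaussian parameterized by its FWHM, same apex convention as
    :func:`lorentzian`."""
    return amplitude * np.exp(-4.0 * _LN2 * (nu - center) ** 2 / fwhm**2) + offset


_MODELS = {"lorentzian": lorentzian, "gaussian": gaussian}


@dataclass
class PeakModel:
    kind: str
    amplitude: float
    center: float
    fwhm: float
    offset: float

    def __call__(self, nu):
        return _MODELS[self.kind](nu, self.amplitude, self.center, self.fwhm, self.offset)


@dataclass
class PeakFitResult:
    """Fitted line-shape parameters plus quality metrics for one peak."""

    model: PeakModel
    shift: float
    fwhm: float
    rms: float
    r_squared: float
    n_channels: int
    converged: bool
    side: str

    @property
    def kind(self) -> str:
        return self.model.kind


@dataclass
class CombinedResult:
    """Stokes / anti-Stokes combination with asymmetry QC metrics."""

    shift: float
    fwhm: float
    shift_asymmetry: float
    fwhm_asymmetry: float
    qc_flags: list[str] = field(default_factory=list)
    stokes: PeakFitResult | None = None
    anti_stokes: PeakFitResult | None = None


def _initial_guess(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    apex = int(np.argmax(y))
    offset = float((y[0] + y[-1]) / 2.0)
    amplitude = max(float(y[apex] - offset), 1e-12)
    half_level = offset + amplitude / 2.0
    above = np.flatnonzero(y >= half_level)
    if above.size >= 2:
        fwhm = abs(float(x[above[-1]] - x[above[0]]))
    else:
        fwhm = 0.0
    span = abs(float(x[-1] - x[0]))
    if not fwhm > 0:
        fwhm = span / 4.0 if span > 0 else 1.0
    return {
        "amplitude": amplitude,
        "center": float(x[apex]),
        "fwhm": fwhm,
        "offset": offset,
    }


def fit_peak(
    spectrum: CalibratedSpectrum,
    segment: PeakSegment,
    kind: str = "lorentzian",
    pad: int = 0,
    max_nfev: int = 200,
    xtol: float = 1e-8,
) -> PeakFitResult:
    """Fit one line shape to a peak segment of a calibrated spectrum.

    ``pad`` widens the fitted window by that many channels on each side of
    the segment so the baseline offset is constrained by the peak wings;
    the window is clipped to the spectrum.  Non-convergence within the
    iteration budget is reported through ``converged`` with the last
    parameter values still returned; a window shorter than 5 channels (4
    parameters + 1) raises.
    """
    if kind not in _MODELS:
        raise FitError(f"unknown model kind {kind!r}; use one of {sorted(_MODELS)}")
    lo = max(segment.start - pad, 0)
    hi = min(segment.stop + pad, spectrum.intensities.size - 1)
    x = spectrum.frequencies[lo : hi + 1]
    y = spectrum.intensities[lo : hi + 1]
    n = x.size
    if n < 5:
        raise FitError(f"segment spans {n} channels; at least 5 are required")

    guess = _initial_guess(x, y)
    model = Model(_MODELS[kind], independent_vars=["nu"])
    params = model.make_params(**guess)
    params["amplitude"].set(min=1e-12)
    fwhm_max = spectrum.fsr / 2.0 if spectrum.fsr > 0 else np.inf
    params["fwhm"].set(min=1e-9, max=fwhm_max)
    params["center"].set(min=float(np.min(x)), max=float(np.max(x)))
    result = model.fit(y, params, nu=x, max_nfev=max_nfev, fit_kws={"xtol": xtol})

    best = {name: float(result.params[name].value) for name in guess}
    residuals = y - model.eval(result.params, nu=x)
    rms = float(np.sqrt(np.mean(residuals**2)))
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else float(ss_res == 0.0)

    return PeakFitResult(
        model=PeakModel(kind=kind, **best),
        shift=best["center"],
        fwhm=best["fwhm"],
        rms=rms,
        r_squared=r_squared,
        n_channels=n,
        converged=bool(result.success),
        side=segment.side,
    )


def combine_sides(
    stokes: PeakFitResult | None,
    anti_stokes: PeakFitResult | None,
    mode: str = "mean",
) -> CombinedResult:
    """Combine the Stokes and anti-Stokes fits of one spectrum.

    ``mode`` "mean" averages shift and width over the two sides (the
    Stokes/anti-Stokes asymmetry is retained as a QC metric); "stokes" /
    "anti_stokes" report one side only.  A missing or unconverged side
    flags the result and falls back to the usable side.
    """
    if mode not in ("mean", "stokes", "anti_stokes"):
        raise FitError(f"unknown combination mode {mode!r}")
    flags: list[str] = []

    def usable(res, label):
        if res is None:
            flags.append(f"{label}_missing")
            return None
        if not res.converged:
            flags.append(f"{label}_unconverged")
            return None
        return res

    s = usable(stokes, "stokes")
    a = usable(anti_stokes, "anti_stokes")
    if mode == "stokes":
        a = None
        flags = [f for f in flags if not f.startswith("anti_stokes")]
    elif mode == "anti_stokes":
        s = None
        flags = [f for f in flags if not f.startswith("stokes")]

    if s is not None and a is not None:
        shift = (s.shift + a.shift) / 2.0
        fwhm = (s.fwhm + a.fwhm) / 2.0
        shift_asym = abs(s.shift - a.shift)
        fwhm_asym = abs(s.fwhm - a.fwhm)
    elif s is not None or a is not None:
        one = s if s is not None else a
        shift, fwhm = one.shift, one.fwhm
        shift_asym = fwhm_asym = float("nan")
        if mode == "mean":
            flags.append("single_side")
    else:
        shift = fwhm = shift_asym = fwhm_asym = float("nan")
        flags.append("no_converged_fit")

    return CombinedResult(
        shift=shift,
        fwhm=fwhm,
        shift_asymmetry=shift_asym,
        fwhm_asymmetry=fwhm_asym,
        qc_flags=flags,
        stokes=stokes,
        anti_stokes=anti_stokes,
    )
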