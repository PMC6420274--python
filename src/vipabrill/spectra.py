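"""Spectral extraction, frequency calibration and peak segmentation.

After registration the spectral data lie on the top-left to bottom-right
diagonal of the canonical square, bounded by two Rayleigh peaks one free
spectral range apart.  A band around that diagonal is resampled so the
dispersion axis coincides with the x-axis (the 45 degree anticlockwise
rotation of the raw protocol), each column's maximum gives one spectral
channel, and the channel axis is converted to GHz through

    nu(i) = FSR * min(i - R0, R1 - i) / (R1 - R0)

where R0, R1 are the Rayleigh positions on the channel axis.  The min()
folds the down-shifted Stokes and up-shifted anti-Stokes peaks onto a
common positive-shift axis that is 0 at the Rayleigh lines and FSR/2 at
the midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fixtures import SPECTRAL_DIAGONAL


class SpectrumError(ValueError):
    pass


@dataclass
class Spectrum:
    """1-D trace on the pixel/channel axis, bounded by Rayleigh positions
    ``r0 < r1`` (sub-pixel, in channel units)."""

    intensities: np.ndarray
    r0: float
    r1: float

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float).ravel()
        if not self.r0 < self.r1:
            raise SpectrumError(f"require r0 < r1; got {self.r0}, {self.r1}")

    @property
    def channels(self) -> np.ndarray:
        return np.arange(self.intensities.size)


@dataclass
class CalibratedSpectrum:
    """1-D trace with a GHz frequency axis (folded, in [0, FSR/2])."""

    frequencies: np.ndarray
    intensities: np.ndarray
    fsr: float
    r0: float = 0.0
    r1: float = 0.0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float).ravel()
        self.intensities = np.asarray(self.intensities, dtype=float).ravel()
        if self.frequencies.size != self.intensities.size:
            raise SpectrumError("frequency and intensity axes differ in length")


@dataclass
class PeakSegment:
    """Maximal run of above-threshold channels: one candidate peak.

    ``start``/``stop`` are inclusive channel indices; ``side`` labels the
    segment Stokes (nearer R0) or anti-Stokes (nearer R1) by the position
    of its apex relative to the spectrum midpoint.
    """

    start: int
    stop: int
    apex_channel: int
    apex_intensity: float
    side: str

    def __post_init__(self) -> None:
        if not self.start <= self.apex_channel <= self.stop:
            raise SpectrumError("segment apex must lie inside its range")

    @property
    def n_channels(self) -> int:
        return self.stop - self.start + 1


# ---------------------------------------------------------------------------


def extract_band(
    warped: np.ndarray,
    canonical: np.ndarray,
    band_halfwidth: int = 10,
    order: int = 1,
) -> np.ndarray:
    """Resample the strip around the spectral diagonal of a registered frame.

    Rows of the returned band are perpendicular offsets in
    [-band_halfwidth, band_halfwidth]; columns sample the top-left to
    bottom-right diagonal at ~1 px spacing, so the dispersion axis is the
    x-axis and the bounding Rayleigh peaks sit at the first and last
    columns.  Bilinear sampling is the default: spline orders reconstruct
    smooth line shapes slightly more faithfully but ring at the edges of
    the clipped (saturated) Rayleigh regions, which can fabricate peak
    candidates near the spectrum ends.
    """
    warped = np.asarray(warped, dtype=float)
    canonical = np.asarray(canonical, dtype=float).reshape(4, 2)
    p0, p1 = canonical[SPECTRAL_DIAGONAL[0]], canonical[SPECTRAL_DIAGONAL[1]]
    length = float(np.hypot(*(p1 - p0)))
    if length <= 1:
        raise SpectrumError("diagonal corners coincide")
    n_channels = int(round(length)) + 1
    e = (p1 - p0) / length
    perp = np.array([-e[1], e[0]])
    s = np.linspace(0.0, length, n_channels)
    offsets = np.arange(-band_halfwidth, band_halfwidth + 1, dtype=float)
    rows = p0[0] + np.outer(offsets, np.full(n_channels, 1.0)) * perp[0] + s * e[0]
    cols = p0[1] + np.outer(offsets, np.full(n_channels, 1.0)) * perp[1] + s * e[1]
    if (
        rows.min() < 0
        or cols.min() < 0
        or rows.max() > warped.shape[0] - 1
        or cols.max() > warped.shape[1] - 1
    ):
        raise SpectrumError(
            f"band of half-width {band_halfwidth} px exceeds the frame bounds"
        )
    return ndimage.map_coordinates(warped, [rows, cols], order=order, mode="constant")


def project_max(band: np.ndarray) -> Spectrum:
    """Column-maximum projection: one channel per band column, intensity =
    the maximum over that column's pixels."""
    band = np.asarray(band, dtype=float)
    if band.ndim != 2 or band.size == 0:
        raise SpectrumError("band must be a non-empty 2-D image")
    return Spectrum(band.max(axis=0), r0=0.0, r1=float(band.shape[1] - 1))


def calibrate(spectrum: Spectrum, fsr: float) -> CalibratedSpectrum:
    """Convert the channel axis to a GHz Brillouin-shift axis.

    nu(i) = fsr * min(i - r0, r1 - i) / (r1 - r0): zero at both Rayleigh
    positions, fsr/2 at the midpoint, piecewise linear in between; Stokes
    and anti-Stokes fold onto the same positive axis.
    """
    if fsr <= 0:
        raise SpectrumError("fsr must be positive")
    if not spectrum.r0 < spectrum.r1:
        raise SpectrumError("require r0 < r1")
    i = spectrum.channels.astype(float)
    nu = fsr * np.minimum(i - spectrum.r0, spectrum.r1 - i) / (spectrum.r1 - spectrum.r0)
    return CalibratedSpectrum(
        frequencies=nu,
        intensities=spectrum.intensities,
        fsr=fsr,
        r0=spectrum.r0,
        r1=spectrum.r1,
    )


def segment_peaks(
    spectrum: Spectrum | CalibratedSpectrum,
    window_halfwidth: int = 10,
    exclusion: int = 5,
    threshold_multiplier: float = 1.0,
) -> list[PeakSegment]:
    """Separate candidate peaks from background by a local-average threshold.

    A channel is signal when its intensity exceeds ``threshold_multiplier``
    times the mean of the surrounding ``window_halfwidth`` channels on each
    side (centre excluded); maximal runs of adjacent signal channels form
    segments.  Channels within ``exclusion`` channels of the Rayleigh
    positions are masked first, keeping the saturated Rayleigh skirts out
    of the candidates.
    """
    if window_halfwidth < 1:
        raise SpectrumError("window_halfwidth must be >= 1")
    y = spectrum.intensities
    n = y.size
    if n < 2 * window_halfwidth + 1:
        raise SpectrumError("spectrum shorter than the averaging window")
    size = 2 * window_halfwidth + 1
    local_sum = ndimage.uniform_filter1d(y, size=size, mode="nearest") * size
    surround_mean = (local_sum - y) / (size - 1)
    signal = y > threshold_multiplier * surround_mean

    i = np.arange(n, dtype=float)
    r0, r1 = spectrum.r0, spectrum.r1
    signal &= (i - r0 >= exclusion) & (r1 - i >= exclusion)

    midpoint = (r0 + r1) / 2.0
    segments: list[PeakSegment] = []
    padded = np.concatenate([[False], signal, [False]]).astype(np.int8)
    d = np.diff(padded)
    for a, b in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
        apex = a + int(np.argmax(y[a:b]))
        segments.append(
            PeakSegment(
                start=int(a),
                stop=int(b - 1),
                apex_channel=int(apex),
                apex_intensity=float(y[apex]),
                side="stokes" if apex < midpoint else "anti_stokes",
            )
        )
    return segments
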