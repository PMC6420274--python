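"""Synthetic dual-VIPA spectrometer frames with exact ground truth.

A crossed-VIPA Brillouin spectrometer images each laser spectrum as a
square pattern on the detector: the elastically scattered (Rayleigh) light
saturates the camera at the four corners of the square and blooms into
bright horizontal/vertical lines, while the inelastic Stokes and
anti-Stokes Brillouin doublet sits on the main diagonal between two
adjacent diffraction orders.  This module renders that pattern
analytically, so every downstream stage — thresholding, corner
localization, homography correction, spectral extraction, frequency
calibration and line-shape fitting — can be tested against a known truth.

The geometry is rendered in an undistorted "nominal" coordinate system and
mapped to detector pixels through an affine distortion (laser drift /
pattern shear).  Rendering uses inverse mapping of the analytic pattern,
so the distorted frame carries no interpolation error and the true corner
and peak positions are known to machine precision.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

#: corner ordering convention shared by every module: row/col coordinates,
#: origin at the top-left pixel centre, 0-based
CORNER_ORDER = ("top_left", "top_right", "bottom_right", "bottom_left")

#: the spectral data lie on the diagonal from the top-left to the
#: bottom-right Rayleigh peak (indices into CORNER_ORDER)
SPECTRAL_DIAGONAL = (0, 2)

#: identity affine distortion, row-major (a11, a12, t_row, a21, a22, t_col)
IDENTITY_DISTORTION = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)

_DEFAULT_CORNERS = ((56.0, 56.0), (56.0, 456.0), (456.0, 456.0), (456.0, 56.0))


class FixtureError(ValueError):
    """Raised when a ground-truth description violates its invariants."""


@dataclass
class FixtureTruth:
    """Complete ground-truth description of one synthetic frame.

    Parameters
    ----------
    frame_shape : (rows, cols) of the detector frame in pixels.
    corners : four nominal (row, col) Rayleigh-peak positions ordered
        [top-left, top-right, bottom-right, bottom-left]; the detector-frame
        truth is these positions mapped through ``distortion``.
    fsr : free spectral range of the VIPA etalons in GHz; sets the
        frequency span between adjacent Rayleigh peaks.
    brillouin_shift, brillouin_fwhm : injected Brillouin frequency shift
        and linewidth (FWHM), GHz.
    rayleigh_amplitude : pre-clipping peak height of the Rayleigh spots and
        saturation streaks, detector counts.  Values above
        ``saturation_level`` produce the characteristic clipped plateaus.
    brillouin_amplitude : peak height of each Brillouin peak, counts.
    background_level : constant detector background, counts.
    noise_sigma : standard deviation of additive Gaussian read noise, counts.
    saturation_level : detector full-well clip level, counts.
    distortion : 6 affine coefficients (a11, a12, t_row, a21, a22, t_col)
        mapping nominal (row, col) to detector (row, col); identity by default.
    seed : RNG seed; identical truths generate bit-identical frames.
    """

    brillouin_shift: float
    brillouin_fwhm: float
    frame_shape: tuple[int, int] = (512, 512)
    corners: np.ndarray = _DEFAULT_CORNERS
    fsr: float = 30.0
    rayleigh_amplitude: float = 240_000.0
    brillouin_amplitude: float = 3_000.0
    background_level: float = 100.0
    noise_sigma: float = 60.0
    saturation_level: float = 60_000.0
    distortion: tuple[float, ...] = IDENTITY_DISTORTION
    seed: int = 0
    # rendering geometry (pattern-shape constants, not physics)
    spot_sigma_px: float = 2.5
    streak_halfwidth_px: float = 2.5
    streak_sigma_px: float = 1.0
    cross_sigma_px: float = 2.0

    def __post_init__(self) -> None:
        self.corners = np.asarray(self.corners, dtype=float).reshape(4, 2)
        self.distortion = tuple(float(c) for c in self.distortion)
        self.validate()

    # -- invariants -----------------------------------------------------

    def validate(self) -> None:
        if not 0.0 < self.brillouin_shift < self.fsr / 2.0:
            raise FixtureError(
                f"brillouin_shift must lie in (0, fsr/2) = (0, {self.fsr / 2}); "
                f"got {self.brillouin_shift}"
            )
        if self.brillouin_fwhm <= 0:
            raise FixtureError("brillouin_fwhm must be positive")
        if self.noise_sigma < 0:
            raise FixtureError("noise_sigma must be non-negative")
        if self.fsr <= 0:
            raise FixtureError("fsr must be positive")
        if min(self.frame_shape) < 8:
            raise FixtureError("frame_shape is too small to hold the pattern")
        dc = self.distorted_corners
        rows, cols = self.frame_shape
        if (dc[:, 0] <= 0).any() or (dc[:, 1] <= 0).any() \
                or (dc[:, 0] >= rows - 1).any() or (dc[:, 1] >= cols - 1).any():
            raise FixtureError(
                "corners mapped through the distortion must stay strictly "
                f"inside the frame {self.frame_shape}; got {dc.tolist()}"
            )

    # -- derived geometry -----------------------------------------------

    @property
    def affine(self) -> tuple[np.ndarray, np.ndarray]:
        """Distortion as (2x2 matrix, translation) on (row, col) vectors."""
        a11, a12, tr, a21, a22, tc = self.distortion
        return np.array([[a11, a12], [a21, a22]]), np.array([tr, tc])

    @property
    def distorted_corners(self) -> np.ndarray:
        """True detector-frame corner positions (4, 2), the detection target."""
        A, t = self.affine
        return self.corners @ A.T + t

    @property
    def diagonal_length(self) -> float:
        """Nominal arc length between the two spectral-diagonal corners, px."""
        p0, p1 = self.corners[SPECTRAL_DIAGONAL[0]], self.corners[SPECTRAL_DIAGONAL[1]]
        return float(np.hypot(*(p1 - p0)))

    def peak_arc_positions(self) -> tuple[float, float]:
        """Arc-length positions (px from the top-left corner) of the
        Stokes and anti-Stokes peaks along the spectral diagonal.

        Placed by inverting the frequency-axis relation
        nu = FSR * min(s, L - s) / L, so that calibrating the generator's
        own positions returns ``brillouin_shift`` exactly.
        """
        L = self.diagonal_length
        frac = self.brillouin_shift / self.fsr
        return frac * L, (1.0 - frac) * L

    def peak_positions(self, distorted: bool = True) -> np.ndarray:
        """(2, 2) array of Stokes / anti-Stokes (row, col) peak positions."""
        p0 = self.corners[SPECTRAL_DIAGONAL[0]]
        p1 = self.corners[SPECTRAL_DIAGONAL[1]]
        L = self.diagonal_length
        e = (p1 - p0) / L
        pts = np.array([p0 + s * e for s in self.peak_arc_positions()])
        if distorted:
            A, t = self.affine
            pts = pts @ A.T + t
        return pts

    def replace(self, **changes) -> "FixtureTruth":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# presets

#: (shift GHz, FWHM GHz) literature values used to validate the calibration;
#: the gel preset carries a representative mid-range gelatin hydrogel shift
PRESETS: dict[str, tuple[float, float]] = {
    "methanol": (5.6, 0.7),
    "water": (7.5, 0.65),
    "gel": (8.0, 0.8),
}


def preset(name: str, *, snr: float | None = None, seed: int = 0,
           **overrides) -> FixtureTruth:
    """Build a :class:`FixtureTruth` for a named reference material.

    ``snr`` sets the peak signal-to-noise ratio brillouin_amplitude /
    noise_sigma (default 50); pass ``noise_sigma`` in ``overrides`` to set
    the noise directly, or ``noise_sigma=0`` for a noiseless frame.  Any
    other :class:`FixtureTruth` field can be overridden, e.g. the gel
    preset's shift anywhere in its physically sensible 7-9 GHz range.
    """
    try:
        shift, fwhm = PRESETS[name]
    except KeyError:
        raise FixtureError(
            f"unknown preset {name!r}; available presets: "
            + ", ".join(sorted(PRESETS))
        ) from None
    kwargs = dict(brillouin_shift=shift, brillouin_fwhm=fwhm, seed=seed)
    kwargs.update(overrides)
    truth = FixtureTruth(**kwargs)
    if snr is not None:
        if "noise_sigma" in overrides:
            raise FixtureError("pass either snr or noise_sigma, not both")
        truth = truth.replace(noise_sigma=truth.brillouin_amplitude / snr)
    return truth


def small_truth(name: str = "water", **kwargs) -> FixtureTruth:
    """Reduced-size fixture (160 px frame, 120 px square) for fast tests."""
    kwargs.setdefault("frame_shape", (160, 160))
    kwargs.setdefault(
        "corners", ((20.0, 20.0), (20.0, 140.0), (140.0, 140.0), (140.0, 20.0))
    )
    return preset(name, **kwargs)


def random_drift(rng: np.random.Generator, *, max_translation: float = 5.0,
                 max_shear: float = 0.02,
                 centre: tuple[float, float] = (256.0, 256.0)) -> tuple[float, ...]:
    """Random affine distortion emulating laser drift: a sub-pixel-to-few-px
    translation plus a small shear applied about the frame centre.

    Returns the 6 coefficients in :class:`FixtureTruth` order.
    """
    s1, s2 = rng.uniform(-max_shear, max_shear, size=2)
    t = rng.uniform(-max_translation, max_translation, size=2)
    A = np.array([[1.0, s1], [s2, 1.0]])
    c = np.asarray(centre, dtype=float)
    offset = c - A @ c + t  # shear about the centre, then translate
    return (A[0, 0], A[0, 1], offset[0], A[1, 0], A[1, 1], offset[1])


# ---------------------------------------------------------------------------
# rendering


def _line_distance(u, v, p, q):
    """Perpendicular distance of points (u, v) from the line through p, q."""
    d = q - p
    n = np.array([-d[1], d[0]]) / np.hypot(*d)
    return (u - p[0]) * n[0] + (v - p[1]) * n[1]


def generate_frame(truth: FixtureTruth) -> np.ndarray:
    """Render the synthetic detector frame described by ``truth``.

    The noiseless pattern (background + clipped Rayleigh spots + clipped
    saturation streaks along the four square edges + Lorentzian Brillouin
    ridge on the spectral diagonal) is evaluated analytically at the
    pre-image of every detector pixel under the affine distortion, clipped
    at the saturation level, and Gaussian read noise is added in the
    detector frame.  Identical truths produce bit-identical frames.
    """
    truth.validate()
    rows, cols = truth.frame_shape
    rr, cc = np.meshgrid(np.arange(rows, dtype=float),
                         np.arange(cols, dtype=float), indexing="ij")
    A, t = truth.affine
    Ainv = np.linalg.inv(A)
    dr, dc = rr - t[0], cc - t[1]
    u = Ainv[0, 0] * dr + Ainv[0, 1] * dc
    v = Ainv[1, 0] * dr + Ainv[1, 1] * dc

    signal = np.full((rows, cols), truth.background_level, dtype=float)

    # Rayleigh spots (clipped 2-D Gaussians)
    for r0, c0 in truth.corners:
        signal += truth.rayleigh_amplitude * np.exp(
            -((u - r0) ** 2 + (v - c0) ** 2) / (2.0 * truth.spot_sigma_px**2)
        )

    # saturation streaks: flat-topped ridges along the four square edges
    tl, tr_, br, bl = truth.corners
    for p, q in ((tl, tr_), (bl, br), (tl, bl), (tr_, br)):
        d = _line_distance(u, v, p, q)
        excess = np.maximum(np.abs(d) - truth.streak_halfwidth_px, 0.0)
        signal += truth.rayleigh_amplitude * np.exp(
            -(excess**2) / (2.0 * truth.streak_sigma_px**2)
        )

    # Brillouin doublet: Lorentzian along the spectral diagonal, narrow
    # Gaussian cross-section perpendicular to it
    p0 = truth.corners[SPECTRAL_DIAGONAL[0]]
    p1 = truth.corners[SPECTRAL_DIAGONAL[1]]
    L = truth.diagonal_length
    e = (p1 - p0) / L
    s = (u - p0[0]) * e[0] + (v - p0[1]) * e[1]
    d = (u - p0[0]) * -e[1] + (v - p0[1]) * e[0]
    gamma_px = truth.brillouin_fwhm / truth.fsr * L
    half = gamma_px / 2.0
    profile = np.zeros_like(s)
    for s_peak in truth.peak_arc_positions():
        profile += half**2 / ((s - s_peak) ** 2 + half**2)
    signal += truth.brillouin_amplitude * profile * np.exp(
        -(d**2) / (2.0 * truth.cross_sigma_px**2)
    )

    np.minimum(signal, truth.saturation_level, out=signal)
    if truth.noise_sigma > 0:
        rng = np.random.default_rng(truth.seed)
        signal += rng.normal(0.0, truth.noise_sigma, size=signal.shape)
        np.clip(signal, 0.0, truth.saturation_level, out=signal)
    return signal
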