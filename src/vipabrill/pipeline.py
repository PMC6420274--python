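"""Per-frame orchestration and hyperspectral map assembly.

One frame flows through: denoise -> binarize -> locate_corners ->
compute_transform -> warp -> extract_band -> project_max -> calibrate ->
segment_peaks -> fit_peak (Stokes and anti-Stokes) -> combine_sides.
Stage failures are wrapped with the stage name; a scan-level runner
records failed frames as missing map positions instead of aborting the
scan.  Display enhancement is deliberately absent from this chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import registration, spectra, peakfit
from .registration import CornerSet, AlignmentTransform
from .spectra import CalibratedSpectrum, PeakSegment
from .peakfit import PeakFitResult, CombinedResult

logger = logging.getLogger("vipabrill")


class PipelineError(RuntimeError):
    """A stage failure, carrying the name of the stage that failed."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All tunables of the per-frame chain.

    Units: fsr in GHz; canonical_side, denoise_sigma, refine_halfwidth and
    band_halfwidth in px; segment_window, segment_exclusion and fit_pad in
    spectral channels; binarize_fraction and threshold_multiplier
    dimensionless; alpha is the display-only contrast constant.
    """

    fsr: float = 30.0
    canonical_side: float = 400.0
    denoise_sigma: float = 1.0
    binarize_fraction: float = 0.95
    refine_halfwidth: int = 5
    band_halfwidth: int = 10
    segment_window: int = 10
    segment_exclusion: int = 5
    threshold_multiplier: float = 1.0
    fit_model: str = "lorentzian"
    combine_mode: str = "mean"
    fit_pad: int = 15
    affine_only: bool = False
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.fsr <= 0 or self.canonical_side <= 0:
            raise ValueError("fsr and canonical_side must be positive")
        if not 0.0 < self.binarize_fraction < 1.0:
            raise ValueError("binarize_fraction must lie in (0, 1)")
        if min(self.refine_halfwidth, self.band_halfwidth, self.segment_window) < 1:
            raise ValueError("window half-widths must be >= 1")
        if self.denoise_sigma < 0 or self.segment_exclusion < 0 or self.fit_pad < 0:
            raise ValueError("lengths must be non-negative")


@dataclass
class FrameResult:
    """Everything the chain produced for one frame; intermediate images
    are kept only when requested, so scan processing stays bounded by one
    frame in memory."""

    corners: CornerSet
    transform: AlignmentTransform
    spectrum: CalibratedSpectrum
    segments: list[PeakSegment]
    stokes_fit: PeakFitResult | None
    anti_stokes_fit: PeakFitResult | None
    combined: CombinedResult
    warped: np.ndarray | None = None
    band: np.ndarray | None = None


@dataclass
class FrameFailure:
    stage: str
    message: str


def _select_segments(
    segments: list[PeakSegment],
    spectrum: CalibratedSpectrum,
    exclusion: int,
    margin: int = 0,
    max_apex_fraction: float = 0.8,
) -> dict[str, PeakSegment | None]:
    """Pick one Brillouin candidate per side: the largest-apex segment that
    is not part of a Rayleigh skirt.

    Skirt segments are recognised two ways: they reach within ``margin``
    channels of the Rayleigh exclusion zone (where the local-average
    threshold is still dominated by the elastic line), or their apex sits
    at ``max_apex_fraction`` of the spectrum maximum, i.e. at the
    saturated elastic level rather than an inelastic line shape.
    """
    first = int(np.ceil(spectrum.r0 + exclusion)) + margin
    last = int(np.floor(spectrum.r1 - exclusion)) - margin
    apex_ceiling = max_apex_fraction * float(spectrum.intensities.max())
    chosen: dict[str, PeakSegment | None] = {"stokes": None, "anti_stokes": None}
    for seg in segments:
        if seg.start <= first or seg.stop >= last:
            continue
        if seg.apex_intensity >= apex_ceiling:
            continue
        cur = chosen[seg.side]
        if cur is None or seg.apex_intensity > cur.apex_intensity:
            chosen[seg.side] = seg
    return chosen


def process_frame(
    frame: np.ndarray,
    config: PipelineConfig | None = None,
    keep_intermediates: bool = True,
) -> FrameResult:
    """Run the full quantitative chain on one raw frame.

    Every stage error is re-raised as :class:`PipelineError` naming the
    stage, so scan-level callers can record which step rejected a frame.
    """
    config = config or PipelineConfig()
    frame = np.asarray(frame, dtype=float)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    denoised = stage("denoise", registration.denoise, frame, config.denoise_sigma)
    mask = stage("binarize", registration.binarize, denoised, config.binarize_fraction)
    corners = stage(
        "locate_corners",
        registration.locate_corners,
        mask,
        frame,
        refine_halfwidth=config.refine_halfwidth,
    )
    canonical = registration.canonical_corners(frame.shape, config.canonical_side)
    transform = stage(
        "compute_transform",
        registration.compute_transform,
        corners,
        canonical,
        affine_only=config.affine_only,
    )
    warped = stage("warp", registration.warp, frame, transform)
    band = stage(
        "extract_band", spectra.extract_band, warped, canonical, config.band_halfwidth
    )
    raw_spectrum = stage("project_max", spectra.project_max, band)
    calibrated = stage("calibrate", spectra.calibrate, raw_spectrum, config.fsr)
    segments = stage(
        "segment_peaks",
        spectra.segment_peaks,
        calibrated,
        window_halfwidth=config.segment_window,
        exclusion=config.segment_exclusion,
        threshold_multiplier=config.threshold_multiplier,
    )
    chosen = _select_segments(segments, calibrated, config.segment_exclusion,
                              margin=config.segment_window)

    fits: dict[str, PeakFitResult | None] = {}
    for side_name, seg in chosen.items():
        if seg is None:
            fits[side_name] = None
            continue
        fits[side_name] = stage(
            f"fit_peak[{side_name}]",
            peakfit.fit_peak,
            calibrated,
            seg,
            kind=config.fit_model,
            pad=config.fit_pad,
        )
    combined = stage(
        "combine_sides",
        peakfit.combine_sides,
        fits["stokes"],
        fits["anti_stokes"],
        mode=config.combine_mode,
    )

    logger.info(
        "frame processed: corners=%s combined shift=%.3f GHz fwhm=%.3f GHz flags=%s",
        np.round(corners.corners, 2).tolist(),
        combined.shift,
        combined.fwhm,
        combined.qc_flags,
    )
    return FrameResult(
        corners=corners,
        transform=transform,
        spectrum=calibrated,
        segments=segments,
        stokes_fit=fits["stokes"],
        anti_stokes_fit=fits["anti_stokes"],
        combined=combined,
        warped=warped if keep_intermediates else None,
        band=band if keep_intermediates else None,
    )


# ---------------------------------------------------------------------------
# hyperspectral maps

MAP_COLUMNS = ["x_um", "y_um", "shift_ghz", "fwhm_ghz", "r_squared", "rms", "qc_flags"]


@dataclass
class BrillouinMap:
    """Per-position records of a stage scan; failed positions are present
    with NaN quantities and a ``failed:<stage>`` QC flag."""

    table: pd.DataFrame

    def raster(self, quantity: str) -> np.ndarray:
        """2-D array of ``quantity`` on the (y, x) stage grid (NaN where
        missing)."""
        pivot = self.table.pivot_table(
            index="y_um", columns="x_um", values=quantity, aggfunc="first"
        ).sort_index().sort_index(axis=1)
        return pivot.to_numpy(dtype=float)

    @property
    def n_missing(self) -> int:
        return int(self.table["qc_flags"].str.contains("failed:").sum())


def _mean_quality(result: FrameResult) -> tuple[float, float]:
    fits = [f for f in (result.stokes_fit, result.anti_stokes_fit) if f is not None]
    if not fits:
        return float("nan"), float("nan")
    return (
        float(np.mean([f.r_squared for f in fits])),
        float(np.mean([f.rms for f in fits])),
    )


def assemble_map(
    results: list[FrameResult | FrameFailure],
    positions: list[tuple[float, float]],
) -> BrillouinMap:
    """Assemble per-frame results into a map over stage positions (x, y in
    micrometres).  Duplicate positions are an error; failed frames appear
    as missing records carrying the failing stage."""
    if len(results) != len(positions):
        raise ValueError("results and positions differ in length")
    seen = set()
    rows = []
    for res, (x, y) in zip(results, positions):
        key = (float(x), float(y))
        if key in seen:
            raise ValueError(f"duplicated stage position {key}")
        seen.add(key)
        if isinstance(res, FrameFailure):
            rows.append(
                dict(
                    x_um=key[0], y_um=key[1], shift_ghz=np.nan, fwhm_ghz=np.nan,
                    r_squared=np.nan, rms=np.nan, qc_flags=f"failed:{res.stage}",
                )
            )
            continue
        r2, rms = _mean_quality(res)
        rows.append(
            dict(
                x_um=key[0], y_um=key[1],
                shift_ghz=res.combined.shift, fwhm_ghz=res.combined.fwhm,
                r_squared=r2, rms=rms,
                qc_flags=";".join(res.combined.qc_flags),
            )
        )
    return BrillouinMap(pd.DataFrame(rows, columns=MAP_COLUMNS))


def process_scan(
    frames, positions: list[tuple[float, float]], config: PipelineConfig | None = None
) -> BrillouinMap:
    """Process an iterable of frames (arrays) at the given stage positions.

    Frames are consumed one at a time and only their result records are
    retained; isolated bad frames become missing map records.  Detected
    corner drift relative to the first good frame is logged per frame as
    the drift-correction audit trail.
    """
    config = config or PipelineConfig()
    results: list[FrameResult | FrameFailure] = []
    reference_corners = None
    for i, frame in enumerate(frames):
        try:
            res = process_frame(frame, config, keep_intermediates=False)
        except PipelineError as exc:
            logger.warning("frame %d failed at stage %s: %s", i, exc.stage, exc.cause)
            results.append(FrameFailure(stage=exc.stage, message=str(exc.cause)))
            continue
        if reference_corners is None:
            reference_corners = res.corners.corners
        drift = np.linalg.norm(res.corners.corners - reference_corners, axis=1)
        logger.info("frame %d corner drift vs first frame: %s px",
                    i, np.round(drift, 3).tolist())
        results.append(res)
    return assemble_map(results, positions)


# ---------------------------------------------------------------------------
# elasticity utility


def estimate_modulus(
    shift_ghz: float,
    refractive_index: float,
    mass_density: float,
    wavelength_nm: float,
) -> float:
    """Longitudinal elastic modulus, GPa, from a backscattering Brillouin
    shift via the standard relations v = lambda * nu / (2 n) and M = rho v^2.

    This is the textbook backscattering phonon-velocity relation, supplied
    as a convenience; refractive index (dimensionless) and mass density
    (kg/m^3) must be supplied by the caller — no material defaults are
    assumed.
    """
    if shift_ghz < 0:
        raise ValueError("shift must be non-negative")
    if refractive_index <= 0 or mass_density <= 0 or wavelength_nm <= 0:
        raise ValueError("refractive index, density and wavelength must be positive")
    velocity = wavelength_nm * 1e-9 * shift_ghz * 1e9 / (2.0 * refractive_index)
    return mass_density * velocity**2 / 1e9
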