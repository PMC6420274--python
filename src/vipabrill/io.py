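"""File I/O: 16-bit grayscale TIFF frames, JSON sidecars, CSV tables."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .fixtures import FixtureTruth
from .registration import CornerSet, AlignmentTransform
from .spectra import CalibratedSpectrum
from .peakfit import PeakFitResult, CombinedResult


def read_frame(path) -> np.ndarray:
    """Read a spectrometer frame (grayscale TIFF) as float counts."""
    frame = tifffile.imread(path)
    if frame.ndim != 2:
        raise ValueError(f"{path}: expected a single 2-D grayscale frame")
    return frame.astype(float)


def write_frame(path, frame: np.ndarray) -> None:
    """Write a frame as 16-bit grayscale TIFF (values clipped to uint16)."""
    data = np.clip(np.round(frame), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data)


def write_truth(path, truth: FixtureTruth) -> None:
    d = dataclasses.asdict(truth)
    d["corners"] = np.asarray(truth.corners).tolist()
    Path(path).write_text(json.dumps(d, indent=2))


def read_truth(path) -> FixtureTruth:
    d = json.loads(Path(path).read_text())
    d["frame_shape"] = tuple(d["frame_shape"])
    d["distortion"] = tuple(d["distortion"])
    return FixtureTruth(**d)


def write_corners(path, corners: CornerSet, transform: AlignmentTransform) -> None:
    payload = {
        "corners": corners.corners.tolist(),
        "refinement_residual": corners.refinement_residual,
        "matrix": transform.matrix.tolist(),  # row-major, (row, col, 1) convention
        "canonical_corners": transform.canonical_corners.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_corners(path) -> tuple[CornerSet, AlignmentTransform]:
    d = json.loads(Path(path).read_text())
    corners = CornerSet(
        np.asarray(d["corners"]), refinement_residual=d["refinement_residual"]
    )
    transform = AlignmentTransform(
        matrix=np.asarray(d["matrix"]),
        canonical_corners=np.asarray(d["canonical_corners"]),
    )
    return corners, transform


def write_spectrum(path, spectrum: CalibratedSpectrum) -> None:
    pd.DataFrame(
        {
            "channel": np.arange(spectrum.intensities.size),
            "frequency_ghz": spectrum.frequencies,
            "intensity": spectrum.intensities,
        }
    ).to_csv(path, index=False)


def read_spectrum(path, fsr: float | None = None) -> CalibratedSpectrum:
    df = pd.read_csv(path)
    freq = df["frequency_ghz"].to_numpy(dtype=float)
    if fsr is None:
        fsr = 2.0 * float(freq.max())  # folded axis peaks at FSR/2
    n = len(df) - 1
    return CalibratedSpectrum(
        frequencies=freq,
        intensities=df["intensity"].to_numpy(dtype=float),
        fsr=fsr,
        r0=0.0,
        r1=float(n),
    )


def fit_to_dict(fit: PeakFitResult) -> dict:
    return {
        "kind": fit.kind,
        "amplitude": fit.model.amplitude,
        "center": fit.model.center,
        "fwhm": fit.fwhm,
        "offset": fit.model.offset,
        "shift": fit.shift,
        "rms": fit.rms,
        "r_squared": fit.r_squared,
        "n_channels": fit.n_channels,
        "converged": fit.converged,
        "side": fit.side,
    }


def combined_to_dict(combined: CombinedResult) -> dict:
    out = {
        "shift_ghz": combined.shift,
        "fwhm_ghz": combined.fwhm,
        "shift_asymmetry_ghz": combined.shift_asymmetry,
        "fwhm_asymmetry_ghz": combined.fwhm_asymmetry,
        "qc_flags": combined.qc_flags,
    }
    for label, fit in (("stokes", combined.stokes), ("anti_stokes", combined.anti_stokes)):
        out[label] = fit_to_dict(fit) if fit is not None else None
    return out
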