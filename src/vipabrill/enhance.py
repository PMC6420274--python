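"""Contrast-enhanced pseudo-colour rendering of raw spectrometer frames.

Raw Brillouin frames are dominated by the saturated Rayleigh fiducials;
the weak inelastic signal is invisible on a linear grey scale.  The
normalization here maps intensities within ``alpha`` standard deviations
of the frame mean onto [0, 1] and clamps everything outside, which makes
the Brillouin doublet visible for inspection.  This rendering is display
only: it never feeds the quantitative chain.
"""

from __future__ import annotations

import numpy as np
from matplotlib import colormaps


class EnhanceError(ValueError):
    pass


def contrast_normalize(frame: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Map frame intensities to perceptual values in [0, 1].

    A pixel with intensity I maps to 0 if I < mu - alpha*sigma, to 1 if
    I > mu + alpha*sigma, and linearly in between, where mu and sigma are
    the mean and standard deviation of the whole frame and ``alpha`` in
    (0, 1] sets the displayed dynamic range.

    A constant frame (sigma = 0) raises: it is diagnostic of an
    acquisition failure, not a displayable spectrum.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise EnhanceError("empty frame")
    if not 0.0 < alpha <= 1.0:
        raise EnhanceError(f"alpha must lie in (0, 1]; got {alpha}")
    mu = frame.mean()
    sigma = frame.std()
    if sigma == 0.0:
        raise EnhanceError("constant frame (sigma = 0): cannot normalize")
    return np.clip((frame - mu + alpha * sigma) / (2.0 * alpha * sigma), 0.0, 1.0)


def to_pseudocolour(normalized: np.ndarray, colormap_name: str = "viridis") -> np.ndarray:
    """Convert a [0, 1] intensity grid to an 8-bit RGB image.

    The colour scale is applied monotonically; any perceptually uniform
    matplotlib colormap name is accepted.
    """
    normalized = np.asarray(normalized, dtype=float)
    if normalized.size and (normalized.min() < 0.0 or normalized.max() > 1.0):
        raise EnhanceError("input values must lie in [0, 1]; normalize first")
    cmap = colormaps[colormap_name]
    rgba = cmap(normalized)
    return (rgba[..., :3] * 255.0).round().astype(np.uint8)
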