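"""Rayleigh-corner localization and homography-based drift correction.

The four saturated Rayleigh peaks at the corners of the VIPA square are
used as fiducial markers.  Localization follows a fixed protocol: Gaussian
denoising, thresholding at a fraction of the frame maximum, extraction of
the centre pixels of the saturated lines forming the square's edges,
assignment of those pixels to corners via the mask's centre of gravity,
per-corner least-squares line fits whose intersections give first corner
estimates, and sub-pixel refinement by the intensity-weighted centre of
gravity of the original frame around each intersection.  A projective
transform mapping the detected corners onto a canonical square then
corrects laser drift and pattern distortion for the whole frame.

All coordinates are (row, col), origin at the top-left pixel centre,
0-based; corners are ordered [top-left, top-right, bottom-right,
bottom-left].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform

from .fixtures import CORNER_ORDER


class RegistrationError(RuntimeError):
    """Raised when corner localization or transform estimation fails."""


@dataclass
class CornerSet:
    """Four sub-pixel Rayleigh-peak positions plus a refinement diagnostic.

    ``refinement_residual`` is the mean distance in px between the
    line-intersection estimates and their weighted-centre-of-gravity
    refinements; large values flag a distorted or poorly exposed pattern.
    """

    corners: np.ndarray  # (4, 2) float, [TL, TR, BR, BL]
    refinement_residual: float = 0.0

    def __post_init__(self) -> None:
        self.corners = np.asarray(self.corners, dtype=float).reshape(4, 2)
        if not _is_strictly_convex(self.corners):
            raise RegistrationError(
                "detected corners do not form a strictly convex quadrilateral"
            )


@dataclass
class AlignmentTransform:
    """3x3 projective map from source-frame (row, col) homogeneous
    coordinates to canonical coordinates, plus the canonical targets."""

    matrix: np.ndarray  # (3, 3)
    canonical_corners: np.ndarray  # (4, 2)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.canonical_corners = np.asarray(
            self.canonical_corners, dtype=float
        ).reshape(4, 2)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise RegistrationError("alignment transform is not invertible")

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) source (row, col) points to canonical coordinates."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        h = np.column_stack([pts, np.ones(len(pts))]) @ self.matrix.T
        return h[:, :2] / h[:, 2:3]


def _is_strictly_convex(quad: np.ndarray) -> bool:
    cross = []
    for i in range(4):
        a = quad[(i + 1) % 4] - quad[i]
        b = quad[(i + 2) % 4] - quad[(i + 1) % 4]
        cross.append(a[0] * b[1] - a[1] * b[0])
    cross = np.asarray(cross)
    return bool((cross > 0).all() or (cross < 0).all())


# ---------------------------------------------------------------------------
# pre-processing


def denoise(frame: np.ndarray, sigma_px: float = 1.0) -> np.ndarray:
    """Gaussian noise filter; ``sigma_px = 0`` returns an unchanged copy."""
    if sigma_px < 0:
        raise ValueError("sigma_px must be non-negative")
    frame = np.asarray(frame, dtype=float)
    if sigma_px == 0:
        return frame.copy()
    return ndimage.gaussian_filter(frame, sigma=sigma_px)


def binarize(frame: np.ndarray, fraction: float = 0.95) -> np.ndarray:
    """Threshold at ``fraction`` of the frame maximum.

    On a denoised frame this isolates the saturated Rayleigh spots and
    streaks, i.e. the lines forming the edges of the dispersion square.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    frame = np.asarray(frame, dtype=float)
    return frame >= fraction * frame.max()


# ---------------------------------------------------------------------------
# corner localization


def _runs(line: np.ndarray):
    """Start/stop (exclusive) index pairs of True runs in a 1-D bool array."""
    padded = np.concatenate([[False], line, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return starts, stops


def _edge_centre_pixels(mask: np.ndarray, max_run: int):
    """Centre pixels of the near-horizontal and near-vertical mask lines.

    Scanning column by column, each short run of mask pixels is a section
    through a near-horizontal saturated line and contributes its centre
    (mean row, col); runs longer than ``max_run`` belong to near-vertical
    lines and are skipped.  The row-wise scan does the converse.
    """
    horiz, vert = [], []
    for idx in range(mask.shape[1]):  # column scan -> near-horizontal edges
        starts, stops = _runs(mask[:, idx])
        for a, b in zip(starts, stops):
            if b - a <= max_run:
                horiz.append(((a + b - 1) / 2.0, float(idx)))
    for idx in range(mask.shape[0]):  # row scan -> near-vertical edges
        starts, stops = _runs(mask[idx, :])
        for a, b in zip(starts, stops):
            if b - a <= max_run:
                vert.append((float(idx), (a + b - 1) / 2.0))
    return np.array(horiz).reshape(-1, 2), np.array(vert).reshape(-1, 2)


def _weighted_cog(
    frame: np.ndarray,
    point: np.ndarray,
    halfwidth: int,
    max_iter: int = 10,
    tol: float = 1e-3,
) -> np.ndarray:
    """Intensity-weighted centre of gravity over a (2*halfwidth+1)^2 window
    centred (sub-pixel, bilinear-sampled) at ``point``.

    The estimate is iterated by recentring the window on the previous
    centroid: saturation streaks crossing the window contribute mass that
    follows the window rather than the peak, so a single evaluation is
    pulled toward the initial window centre, while the recentred iteration
    has the symmetric peak position as its fixed point.
    """
    offsets = np.arange(-halfwidth, halfwidth + 1, dtype=float)
    dr, dc = np.meshgrid(offsets, offsets, indexing="ij")
    centre = np.asarray(point, dtype=float).copy()
    for _ in range(max_iter):
        window = ndimage.map_coordinates(
            frame, [centre[0] + dr, centre[1] + dc], order=1, mode="nearest"
        )
        total = window.sum()
        if total <= 0:
            raise RegistrationError("weighted centre of gravity: empty window")
        step = np.array([(window * dr).sum(), (window * dc).sum()]) / total
        centre = centre + step
        if np.hypot(*step) < tol:
            break
    return centre


def _robust_line(x: np.ndarray, y: np.ndarray, n_iter: int = 3):
    """Least-squares line y = a + b*x with MAD-based outlier rejection.

    Stray mask fragments (noise-broken streak edges, inter-order blobs)
    otherwise act as high-leverage points in the edge fits.
    """
    keep = np.ones(x.size, dtype=bool)
    b = a = 0.0
    for _ in range(n_iter):
        if keep.sum() < 2 or np.ptp(x[keep]) == 0:
            break
        b, a = np.polyfit(x[keep], y[keep], 1)
        resid = y - (a + b * x)
        scale = 1.4826 * np.median(np.abs(resid[keep] - np.median(resid[keep])))
        new_keep = np.abs(resid) <= max(3.0 * scale, 1.0)
        if new_keep.sum() < 2 or (new_keep == keep).all():
            keep = new_keep if new_keep.sum() >= 2 else keep
            break
        keep = new_keep
    return a, b


def locate_corners(
    mask: np.ndarray,
    frame: np.ndarray,
    refine_halfwidth: int = 5,
    max_run: int = 25,
    aspect_tolerance: tuple[float, float] = (0.8, 1.25),
) -> CornerSet:
    """Locate the four Rayleigh peaks from a thresholded mask.

    Per-corner horizontal and vertical least-squares line fits through the
    edge-centre pixels (assigned to quadrants about the mask's centre of
    gravity) are intersected, and each intersection is refined by the
    intensity-weighted centre of gravity of the original ``frame`` over a
    (2*refine_halfwidth+1)^2 window.

    Raises :class:`RegistrationError` naming the failed stage when the
    mask is blank, a corner has too few edge pixels, or a line fit is
    degenerate.  The straight-line model assumes the pattern is close to a
    square; a side-length ratio outside ``aspect_tolerance`` only warns.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise RegistrationError("no edge pixels found (blank mask)")
    frame = np.asarray(frame, dtype=float)

    cog = np.array(np.nonzero(mask), dtype=float).mean(axis=1)
    horiz, vert = _edge_centre_pixels(mask, max_run=max_run)
    if horiz.size == 0 or vert.size == 0:
        raise RegistrationError("edge-centre extraction: no usable line pixels")

    def quadrant(pts):
        above = pts[:, 0] < cog[0]
        left = pts[:, 1] < cog[1]
        return {
            "top_left": pts[above & left],
            "top_right": pts[above & ~left],
            "bottom_right": pts[~above & ~left],
            "bottom_left": pts[~above & left],
        }

    hq, vq = quadrant(horiz), quadrant(vert)

    intersections = []
    for name in CORNER_ORDER:
        hp, vp = hq[name], vq[name]
        if len(hp) < 2 or len(vp) < 2:
            raise RegistrationError(
                f"corner {name}: fewer than 2 edge-centre pixels per axis"
            )
        if np.ptp(hp[:, 1]) == 0 or np.ptp(vp[:, 0]) == 0:
            raise RegistrationError(f"corner {name}: degenerate line fit")
        # horizontal edge: row = a + b*col; vertical edge: col = a2 + b2*row
        a, b = _robust_line(hp[:, 1], hp[:, 0])
        a2, b2 = _robust_line(vp[:, 0], vp[:, 1])
        det = 1.0 - b * b2
        if abs(det) < 1e-9:
            raise RegistrationError(f"corner {name}: edge lines nearly parallel")
        r = (a + b * a2) / det
        c = a2 + b2 * r
        intersections.append((r, c))
    intersections = np.asarray(intersections)

    refined = np.array(
        [_weighted_cog(frame, p, refine_halfwidth) for p in intersections]
    )
    residual = float(np.linalg.norm(refined - intersections, axis=1).mean())
    corner_set = CornerSet(refined, refinement_residual=residual)

    sides = np.linalg.norm(np.roll(refined, -1, axis=0) - refined, axis=1)
    ratio = sides.max() / sides.min()
    if ratio > aspect_tolerance[1] or 1.0 / ratio < aspect_tolerance[0]:
        warnings.warn(
            "detected pattern deviates from a square "
            f"(side-length ratio {ratio:.3f}); the straight-line edge "
            "approximation may be inaccurate",
            stacklevel=2,
        )
    return corner_set


# ---------------------------------------------------------------------------
# homography


def canonical_corners(frame_shape: tuple[int, int], side: float) -> np.ndarray:
    """Corners of a centred, axis-aligned canonical square of given side.

    Margins are rounded to integer pixels so that a frame already on the
    canonical grid is warped without sub-pixel resampling.
    """
    rows, cols = frame_shape
    mr, mc = round((rows - side) / 2.0), round((cols - side) / 2.0)
    if mr < 0 or mc < 0 or mr + side > rows - 1 or mc + side > cols - 1:
        raise ValueError("canonical square does not fit inside the frame")
    return np.array(
        [[mr, mc], [mr, mc + side], [mr + side, mc + side], [mr + side, mc]],
        dtype=float,
    )


_SWAP = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])


def compute_transform(
    detected: CornerSet | np.ndarray,
    canonical: np.ndarray,
    affine_only: bool = False,
) -> AlignmentTransform:
    """Exact 4-point homography sending detected corners onto the canonical
    square (``affine_only`` restricts to a least-squares 6-dof affine)."""
    src = detected.corners if isinstance(detected, CornerSet) else np.asarray(detected)
    src = np.asarray(src, dtype=float).reshape(4, 2)
    dst = np.asarray(canonical, dtype=float).reshape(4, 2)
    for quad, label in ((src, "detected"), (dst, "canonical")):
        if not _is_strictly_convex(quad):
            raise RegistrationError(f"{label} corners are degenerate (not convex)")
    tf_cls = sktransform.AffineTransform if affine_only else sktransform.ProjectiveTransform
    if hasattr(tf_cls, "from_estimate"):
        tf = tf_cls.from_estimate(src[:, ::-1], dst[:, ::-1])  # skimage works in (x, y)
        if not tf:
            raise RegistrationError("homography estimation failed")
    else:  # older scikit-image
        tf = tf_cls()
        if not tf.estimate(src[:, ::-1], dst[:, ::-1]):
            raise RegistrationError("homography estimation failed")
    if not np.all(np.isfinite(tf.params)):
        raise RegistrationError("homography estimation failed")
    matrix = _SWAP @ tf.params @ _SWAP
    return AlignmentTransform(matrix=matrix, canonical_corners=dst)


def warp(
    frame: np.ndarray,
    transform: AlignmentTransform,
    output_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Resample ``frame`` onto the canonical grid.

    Inverse mapping with bilinear interpolation; pixels whose pre-image
    falls outside the source frame are zero-filled.  An exact identity
    transform returns the frame unchanged.
    """
    frame = np.asarray(frame, dtype=float)
    if output_shape is None:
        output_shape = frame.shape
    if np.array_equal(transform.matrix, np.eye(3)) and output_shape == frame.shape:
        return frame.copy()
    tf = sktransform.ProjectiveTransform(_SWAP @ transform.matrix @ _SWAP)
    return sktransform.warp(
        frame,
        inverse_map=tf.inverse,
        output_shape=output_shape,
        order=1,
        mode="constant",
        cval=0.0,
        preserve_range=True,
    )
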