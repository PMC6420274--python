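"""Corner localization and homography correction against generator truth."""

import numpy as np
import pytest

from vipabrill import fixtures
from vipabrill.fixtures import generate_frame, small_truth
from vipabrill.registration import (
    AlignmentTransform,
    CornerSet,
    RegistrationError,
    binarize,
    canonical_corners,
    compute_transform,
    denoise,
    locate_corners,
    warp,
)


def _detect(frame, **kwargs):
    mask = binarize(denoise(frame, 1.0), 0.95)
    return locate_corners(mask, frame, **kwargs)


# ---------------------------------------------------------------------------
# denoise / binarize


def test_denoise_zero_sigma_is_identity(small_frame):
    out = denoise(small_frame, 0.0)
    assert np.array_equal(out, small_frame)
    assert out is not small_frame  # a copy, not an alias


def test_denoise_conserves_impulse_mass():
    frame = np.zeros((41, 41))
    frame[20, 20] = 500.0
    blurred = denoise(frame, 1.5)
    assert blurred.sum() == pytest.approx(500.0)
    assert blurred[20, 20] < 500.0


def test_denoise_reduces_noise_variance():
    """Per-pixel variance over seeded noisy frames strictly drops."""
    raw, filtered = [], []
    for seed in range(100):
        frame = generate_frame(small_truth("water", snr=20, seed=seed))
        raw.append(frame)
        filtered.append(denoise(frame, 1.0))
    # interior background region, away from pattern structure
    sl = (slice(60, 100), slice(30, 45))
    var_raw = np.var(np.stack([f[sl] for f in raw]), axis=0).mean()
    var_flt = np.var(np.stack([f[sl] for f in filtered]), axis=0).mean()
    assert var_flt < var_raw


def test_binarize_threshold_arithmetic():
    frame = np.array([[1000.0, 949.0, 951.0, 0.0]])
    mask = binarize(frame, 0.95)
    assert mask.tolist() == [[True, False, True, False]]


def test_binarize_constant_frame_all_true():
    assert binarize(np.full((3, 3), 5.0)).all()


def test_binarize_isolates_rayleigh_structure(small_truth, small_frame):
    """The 0.95 mask covers the corners but none of the Brillouin peaks."""
    mask = binarize(denoise(small_frame, 1.0), 0.95)
    for r, c in np.round(small_truth.corners).astype(int):
        assert mask[r, c]
    for r, c in np.round(small_truth.peak_positions()).astype(int):
        assert not mask[r, c]


# ---------------------------------------------------------------------------
# locate_corners


def test_corners_recovered_on_noiseless_fixture(water_truth, water_frame):
    detected = _detect(water_frame)
    err = np.linalg.norm(detected.corners - water_truth.corners, axis=1)
    assert err.max() < 0.5


def test_translation_equivariance(water_truth):
    """Translating the pattern moves every detected corner by the same
    offset (within 0.2 px)."""
    base = _detect(generate_frame(water_truth)).corners
    shifted_truth = water_truth.replace(distortion=(1, 0, 3.2, 0, 1, -1.7))
    shifted = _detect(generate_frame(shifted_truth)).corners
    delta = shifted - base
    assert np.allclose(delta, [3.2, -1.7], atol=0.2)


def test_blank_mask_reports_no_edge_pixels(small_frame):
    with pytest.raises(RegistrationError, match="no edge pixels"):
        locate_corners(np.zeros_like(small_frame, dtype=bool), small_frame)


def test_partial_mask_reports_missing_corner(small_frame):
    mask = np.zeros_like(small_frame, dtype=bool)
    mask[20, 10:40] = True  # a single horizontal fragment
    with pytest.raises(RegistrationError):
        locate_corners(mask, small_frame)


def test_weighted_cog_oracle_equivalence(water_truth, water_frame):
    """Corner refinement agrees with a brute-force intensity-weighted
    centroid computed over a window centred on each true corner."""
    detected = _detect(water_frame).corners
    for truth_corner, found in zip(water_truth.corners, detected):
        r, c = int(round(truth_corner[0])), int(round(truth_corner[1]))
        win = water_frame[r - 5 : r + 6, c - 5 : c + 6]
        rows, cols = np.mgrid[r - 5 : r + 6, c - 5 : c + 6]
        oracle = np.array(
            [(win * rows).sum() / win.sum(), (win * cols).sum() / win.sum()]
        )
        assert np.linalg.norm(found - oracle) < 0.25


def test_nonconvex_corner_set_rejected():
    with pytest.raises(RegistrationError, match="convex"):
        CornerSet(np.array([[0, 0], [10, 10], [0, 10], [10, 0]]))


# ---------------------------------------------------------------------------
# compute_transform / warp


def test_identity_when_detected_equals_canonical():
    quad = canonical_corners((512, 512), 400)
    tf = compute_transform(quad, quad)
    assert np.allclose(tf.matrix / tf.matrix[2, 2], np.eye(3), atol=1e-9)


def test_pure_translation_transform():
    quad = canonical_corners((512, 512), 400)
    tf = compute_transform(quad + 5.0, quad)
    mapped = tf.apply(quad + 5.0)
    assert np.allclose(mapped, quad, atol=1e-9)
    # mapping direction subtracts the shift
    m = tf.matrix / tf.matrix[2, 2]
    assert np.allclose(m[:2, 2], [-5.0, -5.0], atol=1e-9)


def test_affine_round_trip_synthesize_and_solve():
    rng = np.random.default_rng(5)
    quad = canonical_corners((512, 512), 400)
    for _ in range(10):
        A = np.eye(2) + rng.uniform(-0.05, 0.05, (2, 2))
        t = rng.uniform(-10, 10, 2)
        moved = quad @ A.T + t
        tf = compute_transform(moved, quad)
        assert np.abs(tf.apply(moved) - quad).max() < 1e-6


def test_degenerate_corners_rejected():
    collinear = np.array([[0.0, 0.0], [0.0, 5.0], [0.0, 10.0], [10.0, 0.0]])
    with pytest.raises(RegistrationError):
        compute_transform(collinear, canonical_corners((512, 512), 400))


def test_warp_identity_is_bit_exact(small_frame):
    tf = AlignmentTransform(np.eye(3), canonical_corners(small_frame.shape, 120))
    assert np.array_equal(warp(small_frame, tf), small_frame)


def test_warp_integer_translation_moves_impulse():
    frame = np.zeros((32, 32))
    frame[10, 12] = 7.0
    matrix = np.eye(3)
    matrix[0, 2], matrix[1, 2] = 4.0, -3.0  # source + (4, -3) in canonical
    tf = AlignmentTransform(matrix, canonical_corners((32, 32), 20))
    out = warp(frame, tf)
    assert out[14, 9] == pytest.approx(7.0)
    assert out.sum() == pytest.approx(7.0)


def test_registration_round_trip_on_distorted_fixture():
    """Warping a drifted frame by its solved transform puts the re-detected
    corners onto the canonical positions within 0.5 px."""
    rng = np.random.default_rng(11)
    truth = fixtures.preset(
        "water", snr=50, seed=11, distortion=fixtures.random_drift(rng)
    )
    frame = generate_frame(truth)
    detected = _detect(frame)
    target = canonical_corners(frame.shape, 400)
    tf = compute_transform(detected, target)
    redetected = _detect(warp(frame, tf))
    assert np.linalg.norm(redetected.corners - target, axis=1).max() < 0.5


def test_warp_idempotent_on_canonical_frame(water_frame):
    """A frame already on the canonical grid is essentially unmoved."""
    detected = _detect(water_frame)
    target = canonical_corners(water_frame.shape, 400)
    tf = compute_transform(detected, target)
    rewarped = warp(water_frame, tf)
    moved = _detect(rewarped)
    assert np.linalg.norm(moved.corners - detected.corners, axis=1).max() < 0.1
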