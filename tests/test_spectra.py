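"""Band extraction, frequency calibration and peak segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vipabrill.registration import canonical_corners
from vipabrill.spectra import (
    CalibratedSpectrum,
    Spectrum,
    SpectrumError,
    calibrate,
    extract_band,
    project_max,
    segment_peaks,
)


# ---------------------------------------------------------------------------
# extract_band / project_max


def test_diagonal_line_becomes_horizontal():
    frame = np.zeros((64, 64))
    quad = canonical_corners(frame.shape, 40)
    # paint the TL->BR diagonal
    for t in np.linspace(0, 1, 200):
        p = quad[0] + t * (quad[2] - quad[0])
        frame[int(round(p[0])), int(round(p[1]))] = 100.0
    band = extract_band(frame, quad, band_halfwidth=3)
    centre_row = band.shape[0] // 2
    assert (band[centre_row] > 0).mean() > 0.9  # bright along the axis
    assert band[0].max() <= band[centre_row].min() + 100  # off-axis dimmer


def test_band_rayleigh_peaks_at_extremes(water_result):
    band = water_result.band
    spectrum = band.max(axis=0)
    assert spectrum[0] > 0.9 * spectrum.max()
    assert spectrum[-1] > 0.9 * spectrum.max()


def test_band_exceeding_frame_is_an_error():
    frame = np.zeros((64, 64))
    quad = canonical_corners(frame.shape, 40)
    with pytest.raises(SpectrumError, match="bounds"):
        extract_band(frame, quad, band_halfwidth=100)


def test_project_max_takes_column_maxima():
    band = np.array([[1.0, 5.0, 2.0], [4.0, 0.0, 3.0]])
    spec = project_max(band)
    assert spec.intensities.tolist() == [4.0, 5.0, 3.0]
    assert (spec.r0, spec.r1) == (0.0, 2.0)


def test_project_max_row_permutation_invariant():
    rng = np.random.default_rng(2)
    band = rng.random((7, 30))
    permuted = band[rng.permutation(7)]
    assert np.array_equal(
        project_max(band).intensities, project_max(permuted).intensities
    )


# ---------------------------------------------------------------------------
# calibrate


def test_calibration_closed_form_values():
    spec = Spectrum(np.zeros(600), r0=100.0, r1=500.0)
    cal = calibrate(spec, fsr=30.0)
    assert cal.frequencies[100] == pytest.approx(0.0)
    assert cal.frequencies[300] == pytest.approx(15.0)  # midpoint = FSR/2
    assert cal.frequencies[200] == pytest.approx(7.5)  # 30*min(100,300)/400
    assert cal.frequencies[500] == pytest.approx(0.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    r0=st.floats(0, 50),
    span=st.floats(10, 400),
    fsr=st.floats(1, 100),
)
def test_calibration_symmetry_property(r0, span, fsr):
    """nu(i) = nu(r0 + r1 - i) and the maximum is FSR/2 at the midpoint."""
    r1 = r0 + span
    n = int(np.ceil(r1)) + 1
    cal = calibrate(Spectrum(np.zeros(n), r0=r0, r1=r1), fsr=fsr)
    i = np.arange(n, dtype=float)
    mirrored = fsr * np.minimum((r0 + r1 - i) - r0, r1 - (r0 + r1 - i)) / span
    inside = (i >= r0) & (i <= r1)
    assert np.allclose(cal.frequencies[inside], mirrored[inside], atol=1e-9)
    assert cal.frequencies[inside].max() <= fsr / 2 + 1e-9


def test_calibrate_rejects_bad_axis():
    with pytest.raises(SpectrumError):
        Spectrum(np.zeros(10), r0=5.0, r1=5.0)
    with pytest.raises(SpectrumError):
        calibrate(Spectrum(np.zeros(10), r0=0.0, r1=9.0), fsr=-1.0)


# ---------------------------------------------------------------------------
# segment_peaks


def test_flat_spectrum_has_no_segments():
    spec = Spectrum(np.full(100, 10.0), r0=0.0, r1=99.0)
    assert segment_peaks(spec) == []


def test_isolated_spike_yields_single_segment():
    y = np.full(100, 10.0)
    y[50] = 100.0
    segs = segment_peaks(Spectrum(y, r0=0.0, r1=99.0))
    assert len(segs) == 1
    assert segs[0].start == segs[0].stop == segs[0].apex_channel == 50


def test_two_lorentzian_spectrum_segments(water_result, water_truth):
    """The noiseless water spectrum yields Stokes and anti-Stokes segments
    containing the true apex channels."""
    cal = water_result.spectrum
    segs = [s for s in water_result.segments if s.apex_intensity < 0.5 * cal.intensities.max()]
    sides = {s.side for s in segs}
    assert sides == {"stokes", "anti_stokes"}
    n = cal.intensities.size - 1
    frac = water_truth.brillouin_shift / water_truth.fsr
    for side, true_ch in (("stokes", frac * n), ("anti_stokes", (1 - frac) * n)):
        best = max((s for s in segs if s.side == side), key=lambda s: s.apex_intensity)
        assert best.start <= round(true_ch) <= best.stop


def test_segments_are_disjoint_and_inside_unmasked(water_result):
    segs = sorted(water_result.segments, key=lambda s: s.start)
    for a, b in zip(segs, segs[1:]):
        assert a.stop < b.start
    cal = water_result.spectrum
    for s in segs:
        assert s.start >= cal.r0 + 5 and s.stop <= cal.r1 - 5


def test_growing_exclusion_never_adds_segments():
    rng = np.random.default_rng(3)
    y = rng.random(200) + 10.0
    y[60:66] += 5.0
    y[130:137] += 4.0
    spec = Spectrum(y, r0=0.0, r1=199.0)
    counts = [len(segment_peaks(spec, exclusion=e)) for e in (0, 5, 20, 50, 90)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_threshold_multiplier_suppresses_weak_bumps():
    y = np.full(120, 100.0)
    y[40:45] += 3.0   # weak bump
    y[80:85] += 400.0  # strong peak
    spec = Spectrum(y, r0=0.0, r1=119.0)
    strict = segment_peaks(spec, threshold_multiplier=1.5)
    assert all(s.apex_channel in range(80, 85) for s in strict)


def test_short_spectrum_is_an_error():
    with pytest.raises(SpectrumError, match="window"):
        segment_peaks(Spectrum(np.zeros(5), r0=0.0, r1=4.0), window_halfwidth=10)
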