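import numpy as np
import pytest

from vipabrill import fixtures, pipeline


@pytest.fixture(scope="session")
def water_truth():
    """Full-size noiseless water fixture."""
    return fixtures.preset("water", noise_sigma=0.0)


@pytest.fixture(scope="session")
def water_frame(water_truth):
    return fixtures.generate_frame(water_truth)


@pytest.fixture(scope="session")
def small_truth():
    """Reduced-size noiseless water fixture for fast unit tests."""
    return fixtures.small_truth("water", noise_sigma=0.0)


@pytest.fixture(scope="session")
def small_frame(small_truth):
    return fixtures.generate_frame(small_truth)


@pytest.fixture(scope="session")
def small_config():
    """Pipeline configuration matched to the reduced-size fixture geometry."""
    return pipeline.PipelineConfig(
        canonical_side=120.0, band_halfwidth=8, segment_window=6,
        segment_exclusion=4, fit_pad=8,
    )


@pytest.fixture(scope="session")
def water_result(water_frame):
    """Full pipeline output for the noiseless water frame (computed once)."""
    return pipeline.process_frame(water_frame)
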