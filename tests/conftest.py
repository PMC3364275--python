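import numpy as np
import pytest

from bandconn import PipelineConfig, SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """10-subject, 10-ROI cohort with a Band3-localized patient deficit."""
    cfg = SyntheticConfig(
        n_patients=5,
        n_controls=5,
        n_rois=10,
        n_timepoints=140,
        affected_roi_set=(0, 1, 2, 3),
        within_band_coupling=0.6,
        effect_delta=0.4,
        noise_sd=0.5,
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def fast_config():
    """Desk-scale analysis settings used throughout the tests."""
    return PipelineConfig(mode="multi", top_m=8, grid="fast")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
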