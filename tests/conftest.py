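import numpy as np
import pytest

from uwbid.simulate import SimConfig


@pytest.fixture
def ideal_config() -> SimConfig:
    """Ideal clocks, no jitter, no systematic range bias."""
    return SimConfig(
        tag_clock_skew_ppm=0.0,
        anchor_clock_skew_ppm=0.0,
        timestamp_noise_s=0.0,
        range_bias_slope=1.0,
        range_bias_intercept_m=0.0,
        bbox_jitter_px=0.0,
    )


@pytest.fixture
def floor_correspondences():
    """The four-corner registration of the distorted 30 x 20 cm floor target."""
    src = np.array([[214, 28], [877, 328], [16, 584], [686, 765]], dtype=float)
    dst = np.array([[0, 0], [900, 0], [0, 600], [900, 600]], dtype=float)
    return src, dst


@pytest.fixture
def test_point_table():
    """Three surveyed test points with fixes before/after range calibration."""
    real = [(1.6, 3.6), (3.0, 5.0), (4.0, 6.5)]
    before = [(1.655, 3.673), (3.052, 5.08), (4.065, 6.605)]
    after = [(1.626, 3.628), (3.032, 5.034), (4.0281, 6.533)]
    return real, before, after
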