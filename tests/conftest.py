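import numpy as np
import pytest

from cfocus import (OpticalConfig, blank_mask, generate_random_patterns,
                    identity_medium, make_phase_screen, make_pupil_screen)


@pytest.fixture(scope="session")
def tiny_cfg():
    """3x3 superpixels — small enough for exhaustive brute force."""
    return OpticalConfig(pupil_grid=12, superpixel_size=4, field_grid=64)


@pytest.fixture(scope="session")
def small_cfg():
    """16x16 superpixels, fast propagation (~0.5 ms)."""
    return OpticalConfig(pupil_grid=64, superpixel_size=4, field_grid=128)


@pytest.fixture(scope="session")
def desk_cfg():
    """32x32 superpixels on a 256^2 grid."""
    return OpticalConfig.desk()


@pytest.fixture(scope="session")
def small_medium(small_cfg):
    corr = 4 * small_cfg.superpixel_size * small_cfg.focal_pixel_pitch
    return make_phase_screen(small_cfg, corr, 2.0, 10.0, seed=7)


@pytest.fixture(scope="session")
def small_blank(small_cfg):
    return blank_mask(small_cfg.superpixel_grid, small_cfg.superpixel_size)
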