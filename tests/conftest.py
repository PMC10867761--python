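"""Shared fixtures: hand-built pixel rasters and a small synthetic retina."""

import numpy as np
import pytest

from vasctort import BinaryMask, DiscCenter, SynthConfig


@pytest.fixture
def straight_bar_mask() -> BinaryMask:
    """Solid horizontal bar, 5 px tall, 50 px long."""
    pix = np.zeros((20, 60), dtype=bool)
    pix[8:13, 5:55] = True
    return BinaryMask(pix, image_id="bar")


@pytest.fixture
def plus_sign_mask() -> BinaryMask:
    """Two crossing 5-px-wide bars."""
    pix = np.zeros((61, 61), dtype=bool)
    pix[28:33, 5:56] = True
    pix[5:56, 28:33] = True
    return BinaryMask(pix, image_id="plus")


def y_skeleton() -> np.ndarray:
    """Unit-width Y: three arms of 10 px each meeting at one pixel."""
    pix = np.zeros((40, 40), dtype=bool)
    c = (20, 20)
    pix[c] = True
    for k in range(1, 11):
        pix[20 - k, 20] = True  # up
        pix[20 + k, 20 - k] = True  # down-left diagonal
        pix[20 + k, 20 + k] = True  # down-right diagonal
    return pix


@pytest.fixture
def y_skeleton_pixels() -> np.ndarray:
    return y_skeleton()


@pytest.fixture
def small_synth_config() -> SynthConfig:
    """Small, fast phantom for unit tests (6 vessels fit in 360 px)."""
    return SynthConfig(
        image_size=(360, 360),
        n_vessels=6,
        start_radius_px=50.0,
        vessel_length_px=100.0,
        amplitude_px=5.0,
        wavelength_px=50.0,
        seed=11,
    )


@pytest.fixture
def center_disc() -> DiscCenter:
    return DiscCenter(row=20.0, col=20.0, image_id="fix")
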