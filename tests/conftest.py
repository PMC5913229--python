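import numpy as np
import pytest

from exsr.database import build_database
from exsr.grid import CanvasGeometry, LR_PIXEL_NM, SR_PIXEL_NM
from exsr.simulate import make_single_set

# Tiny canvases used throughout the unit tests: an 8-pixel LR field
# (1.28 um) whose up-sampled / SR grid is 40 x 40 pixels.
TINY_LR = CanvasGeometry(8, 8, LR_PIXEL_NM)
TINY_SR = CanvasGeometry(40, 40, SR_PIXEL_NM)


@pytest.fixture(scope="session")
def tiny_examples():
    """Four single-filament example pairs (orientations 0/45/90/135)."""
    return make_single_set(
        angle_stop_deg=135.0, angle_step_deg=45.0, lr_canvas=TINY_LR, sr_canvas=TINY_SR
    )


@pytest.fixture(scope="session")
def tiny_db(tiny_examples):
    return build_database(tiny_examples)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
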