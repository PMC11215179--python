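import numpy as np
import pytest

from mycophen import plate_io, synth


def small_spec(**overrides) -> synth.ColonySpec:
    """A 256-px test plate: 180-px dish (90 mm), 15-mm colony, no noise."""
    base = dict(image_width=256, image_height=256, dish_diameter_px=180.0,
                colony_semi_axis_h=15.0, colony_semi_axis_v=15.0)
    base.update(overrides)
    return synth.ColonySpec(**base)


@pytest.fixture(scope="session")
def small_plate():
    spec = small_spec()
    img, truth = synth.render_plate(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def small_calib(small_plate):
    """Ground-truth-based calibration for the small plate (detection not under test)."""
    _, _, truth = small_plate
    return plate_io.detect_dish(
        np.zeros_like(truth.dish_mask, dtype=np.uint8),
        detector="provided_mask", dish_mask=truth.dish_mask)


@pytest.fixture(scope="session")
def big_plate():
    """The full-size camera frame: 1280x980 px, 800-px 90-mm dish, 15-mm colony."""
    spec = synth.ColonySpec()
    img, truth = synth.render_plate(spec)
    return spec, img, truth
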