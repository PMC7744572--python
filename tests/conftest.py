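import numpy as np
import pytest

from cortexmap import synthio


@pytest.fixture(scope="session")
def two_area_phantom():
    """Small flat two-area phantom shared across tests."""
    cfg = synthio.RenderConfig(
        resolution_um_per_px=4.0, width_px=448, height_px=320,
        cortical_thickness_um=1000.0, geometry="flat", noise_sd=4.0, seed=7,
    )
    return synthio.render_phantom(
        [synthio.make_preset_profile("hOc1-like"),
         synthio.make_preset_profile("hOc2-like")], cfg,
    )


@pytest.fixture(scope="session")
def arc_phantom():
    cfg = synthio.RenderConfig(
        resolution_um_per_px=4.0, width_px=448, height_px=320,
        cortical_thickness_um=800.0, geometry="arc", noise_sd=0.0, seed=11,
    )
    return synthio.render_phantom(
        [synthio.make_preset_profile("hOc1-like")], cfg,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
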