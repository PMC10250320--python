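import numpy as np
import pytest

from borealtrend.landscape import LandscapeConfig, generate_landscape

#: coarse grid keeps fixture generation fast; 2x2 pixels per 0.05-degree plot
SMALL_KW = dict(resolution=0.025, seed=7)


@pytest.fixture(scope="session")
def small_bundle():
    """Default-structured landscape on a coarse 0.05-degree grid."""
    return generate_landscape(LandscapeConfig(**SMALL_KW))


@pytest.fixture(scope="session")
def small_plot_table(small_bundle):
    from borealtrend.pipeline import build_plot_table
    from borealtrend.sampling import draw_transects
    transects = draw_transects(small_bundle.boundaries, 150.0, seed=7)
    return build_plot_table(small_bundle, transects)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
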