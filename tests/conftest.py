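import numpy as np
import pytest

import cellcov as cc


@pytest.fixture(scope="session")
def fb():
    return cc.load_filter_bank()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def blob_fixture():
    """One oriented-texture image of the default benchmark plus its truth mask."""
    spec = cc.default_spec(n_images=2, seed=0)
    img, truth = cc.generate_image(spec, "lineA-epi30", 42)
    return img, truth


def grating(theta_deg, f=0.18, shape=(256, 256), amp=0.4):
    """Sinusoid whose stripes run at +theta degrees on the displayed image."""
    th = np.deg2rad(theta_deg)
    r, c = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    return 0.5 + amp * np.sin(2 * np.pi * f * (r * np.cos(th) + c * np.sin(th)))
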