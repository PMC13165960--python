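import numpy as np
import pytest

from hueprior.synthetic_scenes import SceneSpec, render_scene


@pytest.fixture(scope="session")
def warm_scene():
    """One deterministic greenhouse scene with per-pixel debug info."""
    spec = SceneSpec(environment="greenhouse", n_objects=6, seed=42)
    image, labels, debug = render_scene(spec, return_debug=True)
    return image, labels, debug


@pytest.fixture(scope="session")
def cool_scene():
    """One deterministic automated-house (cool hue regime) scene."""
    spec = SceneSpec(environment="automated", n_objects=6, seed=43)
    image, labels, debug = render_scene(spec, return_debug=True)
    return image, labels, debug


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
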