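import numpy as np
import pytest

from nucleoseg import SceneSpec, render_scene


@pytest.fixture(scope="session")
def control_scene():
    """One deterministic noise-free control field shared across tests."""
    images, truth = render_scene(SceneSpec(seed=3))
    return images, truth


@pytest.fixture(scope="session")
def noisy_scene():
    """Same panel at moderate noise (sigma 200 ≈ SNR 5 on the markers)."""
    images, truth = render_scene(SceneSpec(seed=3, noise_sigma=200.0))
    return images, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
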