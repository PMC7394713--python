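import numpy as np
import pytest

from trichocount import PreprocessConfig, SceneSpec, generate_scene
from trichocount.cli import run_methods_on_scene


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def default_pre():
    return PreprocessConfig()


@pytest.fixture
def clean_scene():
    """A noiseless, non-occluding 12-trichome scene and its truth."""
    spec = SceneSpec.noiseless(12, seed=7)
    img, truth = generate_scene(spec)
    return spec, img, truth


@pytest.fixture
def run_all():
    return run_methods_on_scene
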